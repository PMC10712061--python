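"""Nine multivariate sequence encodings for site-centered DNA windows.

Three time-series codes — spectral (integer per base), chaos game
representation (iterated midpoints inside the unit square), and the Z-curve
(cumulative purine/amino/weak-bond excess, signed-root compressed) — plus
three gene-feature codes — one-hot position features (BPF), nucleotide
chemical properties (NCP) and dinucleotide physicochemical properties (DPCP)
— and their three row-stacked fusions:

====== ========================== ==========
scheme content                    channels
====== ========================== ==========
code1  spectral                   1
code2  CGR (x, y)                 2
code3  Z-curve                    1
code4  code1 + code2 + code3      4
code5  BPF one-hot (A,T,G,C)      4
code6  NCP (ring, bond, amino)    3
code7  DPCP (6 step parameters)   6
code8  code5 + code6 + code7      13
code9  code4 + code8              17
====== ========================== ==========

Every encoder returns a channels x L matrix for a length-L window and is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, DnaRecord

__all__ = [
    "CHANNELS",
    "SCHEMES",
    "EncodingMatrix",
    "DinucPropertyTable",
    "default_property_table",
    "normalize_properties",
    "encode",
    "encode_dataset",
    "encode_spectral",
    "encode_cgr",
    "encode_z",
    "encode_bpf",
    "encode_ncp",
    "encode_dpcp",
]

CHANNELS = {
    "code1": 1,
    "code2": 2,
    "code3": 1,
    "code4": 4,
    "code5": 4,
    "code6": 3,
    "code7": 6,
    "code8": 13,
    "code9": 17,
}
SCHEMES = tuple(CHANNELS)

#: spectral alphabet values (case-insensitive)
SPECTRAL_VALUE = {"A": 1.0, "G": 2.0, "C": 3.0, "T": 4.0}

#: CGR square vertices
CGR_VERTEX = {
    "A": (1.0, 1.0),
    "G": (-1.0, 1.0),
    "C": (1.0, -1.0),
    "T": (-1.0, -1.0),
}

PROPERTY_NAMES = ("twist", "tilt", "roll", "shift", "slide", "rise")

_DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass(frozen=True)
class EncodingMatrix:
    """A channels x L real matrix produced by one encoding scheme."""

    scheme: str
    values: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("encoding values must be a 2-D matrix")
        if values.shape[0] != len(self.channel_labels):
            raise ValueError("one channel label per matrix row is required")
        expected = CHANNELS.get(self.scheme)
        if expected is not None and values.shape[0] != expected:
            raise ValueError(
                f"{self.scheme} requires {expected} channels, got {values.shape[0]}"
            )

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.channel_labels))


def _sequence_of(record: DnaRecord | str) -> str:
    seq = record.sequence if isinstance(record, DnaRecord) else str(record).upper()
    if not seq or not set(seq) <= ALPHABET:
        raise ValueError(f"sequence {seq!r} is not over {{A,C,G,T}}")
    return seq


# ---------------------------------------------------------------------------
# time-series codes


def encode_spectral(record: DnaRecord | str) -> EncodingMatrix:
    """Spectral code: a -> 1, g -> 2, c -> 3, t -> 4 (one channel)."""
    seq = _sequence_of(record)
    values = np.array([[SPECTRAL_VALUE[s] for s in seq]])
    return EncodingMatrix("code1", values, ("spectral",))


def encode_cgr(record: DnaRecord | str) -> EncodingMatrix:
    """Chaos game representation: iterated midpoints from the origin.

    Point i is the midpoint of point i-1 (origin for i=0) and the vertex of
    base i: CGR_i = CGR_{i-1} - (CGR_{i-1} - g_i)/2.  Rows are the x and y
    coordinate series; all points lie strictly inside (-1, 1)^2.
    """
    seq = _sequence_of(record)
    points = np.empty((2, len(seq)))
    x = y = 0.0
    for i, s in enumerate(seq):
        vx, vy = CGR_VERTEX[s]
        x = x - (x - vx) / 2.0
        y = y - (y - vy) / 2.0
        points[0, i] = x
        points[1, i] = y
    return EncodingMatrix("code2", points, ("cgr_x", "cgr_y"))


def encode_z(record: DnaRecord | str) -> EncodingMatrix:
    """Z-curve code: signed root of X_i + Y_i + Z_i.

    With cumulative counts A_i, C_i, G_i, T_i up to position i,
    X = (A+G)-(C+T), Y = (A+C)-(G+T), Z = (A+T)-(C+G); their sum equals
    4*A_i - i and is compressed by the signed root sign(s)*sqrt(|s|), which
    keeps the series real for pyrimidine-rich prefixes.
    """
    seq = _sequence_of(record)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    a = np.cumsum(arr == b"A")
    i = np.arange(1, len(seq) + 1)
    s = 4 * a - i
    values = np.sign(s) * np.sqrt(np.abs(s))
    return EncodingMatrix("code3", values[None, :].astype(float), ("z",))


def zcurve_components(record: DnaRecord | str) -> np.ndarray:
    """The (X_i, Y_i, Z_i) integer components for every prefix, shape 3 x L."""
    seq = _sequence_of(record)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    a, c, g, t = (np.cumsum(arr == base) for base in (b"A", b"C", b"G", b"T"))
    return np.stack([(a + g) - (c + t), (a + c) - (g + t), (a + t) - (c + g)])


# ---------------------------------------------------------------------------
# gene-feature codes

_BPF_ROW = {"A": 0, "T": 1, "G": 2, "C": 3}


def encode_bpf(record: DnaRecord | str) -> EncodingMatrix:
    """Binary position feature: one-hot columns in row order A, T, G, C."""
    seq = _sequence_of(record)
    values = np.zeros((4, len(seq)))
    for i, s in enumerate(seq):
        values[_BPF_ROW[s], i] = 1.0
    return EncodingMatrix("code5", values, ("bpf_A", "bpf_T", "bpf_G", "bpf_C"))


def encode_ncp(record: DnaRecord | str) -> EncodingMatrix:
    """Nucleotide chemical properties: ring structure (purine {A,G}), hydrogen
    bond strength (weak {A,T}) and functional group (amino {A,C})."""
    seq = _sequence_of(record)
    values = np.zeros((3, len(seq)))
    for i, s in enumerate(seq):
        values[0, i] = float(s in "AG")
        values[1, i] = float(s in "AT")
        values[2, i] = float(s in "AC")
    return EncodingMatrix("code6", values, ("ncp_ring", "ncp_hbond", "ncp_amino"))


def normalize_properties(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each property column to [0, 1]; constant columns map to 0.5."""
    if not np.isfinite(raw.to_numpy(dtype=float)).all():
        raise ValueError("property table contains non-finite values")
    out = {}
    for col in raw.columns:
        x = raw[col].astype(float)
        lo, hi = x.min(), x.max()
        out[col] = (x - lo) / (hi - lo) if hi > lo else pd.Series(0.5, index=x.index)
    return pd.DataFrame(out, index=raw.index)


@dataclass(frozen=True)
class DinucPropertyTable:
    """16 dinucleotides x 6 structural step parameters, raw and normalized.

    The angular parameters (twist, tilt, roll) and translational parameters
    (shift, slide, rise) describe the geometry of one base-pair step; the
    normalized view is min-max scaled per property.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame

    @classmethod
    def from_raw(cls, raw: pd.DataFrame) -> "DinucPropertyTable":
        raw = raw.copy()
        raw.index = [str(d).upper() for d in raw.index]
        missing = set(_DINUCLEOTIDES) - set(raw.index)
        if missing:
            raise ValueError(f"property table missing dinucleotides: {sorted(missing)}")
        if list(raw.columns) != list(PROPERTY_NAMES):
            raw = raw[list(PROPERTY_NAMES)]
        raw = raw.loc[list(_DINUCLEOTIDES)]
        return cls(raw=raw, normalized=normalize_properties(raw))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DinucPropertyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "dinucleotide"
        return cls.from_raw(df)


@lru_cache(maxsize=1)
def default_property_table() -> DinucPropertyTable:
    """The packaged mean B-DNA step-parameter table (crystallographic averages)."""
    source = resources.files("methylcapso").joinpath("data/dinucleotide_properties.tsv")
    with resources.as_file(source) as path:
        return DinucPropertyTable.from_tsv(path)


def encode_dpcp(
    record: DnaRecord | str, table: DinucPropertyTable | None = None
) -> EncodingMatrix:
    """Dinucleotide physicochemical properties, 6 x L.

    Interior positions average the normalized property vectors of the two
    flanking dinucleotides D_{i-1}D_i and D_iD_{i+1}; the first and last
    positions have a single flanking dinucleotide and use it unaveraged.
    """
    seq = _sequence_of(record)
    if len(seq) < 2:
        raise ValueError("DPCP requires sequence length >= 2")
    if table is None:
        table = default_property_table()
    steps = table.normalized.loc[
        [seq[i : i + 2] for i in range(len(seq) - 1)]
    ].to_numpy().T  # 6 x (L-1)
    values = np.empty((6, len(seq)))
    values[:, 0] = steps[:, 0]
    values[:, -1] = steps[:, -1]
    if len(seq) > 2:
        values[:, 1:-1] = (steps[:, :-1] + steps[:, 1:]) / 2.0
    labels = tuple(f"dpcp_{name}" for name in PROPERTY_NAMES)
    return EncodingMatrix("code7", values, labels)


# ---------------------------------------------------------------------------
# dispatch and fusion

_BASE_ENCODERS = {
    "code1": encode_spectral,
    "code2": encode_cgr,
    "code3": encode_z,
    "code5": encode_bpf,
    "code6": encode_ncp,
}

_FUSIONS = {
    "code4": ("code1", "code2", "code3"),
    "code8": ("code5", "code6", "code7"),
    "code9": ("code4", "code8"),
}


def encode(
    record: DnaRecord | str,
    scheme: str = "code9",
    table: DinucPropertyTable | None = None,
) -> EncodingMatrix:
    """Encode one window under any of the nine schemes (fusions row-stack)."""
    if scheme in _BASE_ENCODERS:
        return _BASE_ENCODERS[scheme](record)
    if scheme == "code7":
        return encode_dpcp(record, table)
    if scheme in _FUSIONS:
        parts = [encode(record, part, table) for part in _FUSIONS[scheme]]
        values = np.vstack([p.values for p in parts])
        labels = tuple(label for p in parts for label in p.channel_labels)
        return EncodingMatrix(scheme, values, labels)
    raise ValueError(f"unknown encoding scheme {scheme!r} (use code1..code9)")


def encode_dataset(
    records,
    scheme: str = "code9",
    table: DinucPropertyTable | None = None,
) -> np.ndarray:
    """Encode equal-length records into an (n, channels, L) array."""
    if not records:
        raise ValueError("no records to encode")
    if table is None and scheme in ("code7", "code8", "code9"):
        table = default_property_table()
    mats = [encode(r, scheme, table).values for r in records]
    lengths = {m.shape[1] for m in mats}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed lengths {sorted(lengths)}")
    return np.stack(mats)
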