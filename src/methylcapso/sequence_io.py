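"""Labeled DNA window datasets: FASTA/table I/O, splitting, synthetic generation.

The unit of data is a fixed-length, site-centered DNA window with a binary
label (1 = methylation site, 0 = non-site).  Real benchmark sets in this
problem family ship as FASTA or two-column text; the synthetic generator
emulates their structure by planting a degenerate consensus motif near the
window center of positive records over a composition-matched background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DnaRecord",
    "DatasetSplit",
    "SyntheticConfig",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "split_dataset",
    "generate_synthetic",
]

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DnaRecord:
    """One labeled DNA window.

    Parameters
    ----------
    identifier : str
        Record name, unique within a dataset by convention.
    sequence : str
        Window sequence over {A, C, G, T}; upper-cased on construction.
    label : int
        1 for a methylation site, 0 for a non-site.
    species, mod_type : str, optional
        Free-text provenance tags (e.g. species name; 6mA / 4mC / 5hmC).
    """

    identifier: str
    sequence: str
    label: int
    species: str | None = None
    mod_type: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise ValueError(
                f"record {self.identifier!r}: sequence length {len(seq)} < 2"
            )
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.identifier!r}: characters {sorted(bad)} outside "
                "{A,C,G,T}"
            )
        if self.label not in (0, 1):
            raise ValueError(
                f"record {self.identifier!r}: label {self.label!r} is not 0 or 1"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DatasetSplit:
    """Train/validation/test partition of a record collection."""

    train: tuple[DnaRecord, ...]
    validation: tuple[DnaRecord, ...]
    test: tuple[DnaRecord, ...]
    fractions: tuple[float, float, float]

    @property
    def parts(self) -> tuple[tuple[DnaRecord, ...], ...]:
        return (self.train, self.validation, self.test)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the motif-planting synthetic dataset generator.

    Positives are background sequences (i.i.d. draws from
    ``base_composition``) with ``motif`` written at a fixed position and each
    motif position then mutated, independently with probability
    ``mutation_rate``, to a uniformly chosen *different* base.  Negatives are
    background only.  ``motif_offset`` is the motif start relative to the
    window center; ``None`` centers the motif.
    """

    n_pos: int
    n_neg: int
    length: int = 41
    motif: str = "GAGGTAAC"
    motif_offset: int | None = None
    mutation_rate: float = 0.05
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be non-negative")
        if self.length < 2:
            raise ValueError("window length must be at least 2")
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if not set(motif) <= ALPHABET:
            raise ValueError("motif must be over {A,C,G,T}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any():
            raise ValueError("base_composition must be 4 non-negative numbers")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1 (within 1e-9)")
        start = self.motif_start
        if start < 0 or start + len(motif) > self.length:
            raise ValueError(
                f"motif of length {len(motif)} at offset {self.motif_offset} "
                f"does not fit in a window of length {self.length}"
            )

    @property
    def motif_start(self) -> int:
        offset = self.motif_offset
        if offset is None:
            offset = -(len(self.motif) // 2)
        return self.length // 2 + offset


# ---------------------------------------------------------------------------
# FASTA


def _label_from_record(rec: SeqRecord) -> int | None:
    # description token "label=0|1" wins; then case-insensitive ID prefix
    for token in rec.description.split():
        if token.startswith("label="):
            value = token[len("label=") :]
            if value in ("0", "1"):
                return int(value)
            raise ValueError(
                f"record {rec.id!r}: label token {value!r} is not 0 or 1"
            )
    low = rec.id.lower()
    if low.startswith("pos"):
        return 1
    if low.startswith("neg"):
        return 0
    return None


def _tag_from_description(rec: SeqRecord, key: str) -> str | None:
    for token in rec.description.split():
        if token.startswith(key + "="):
            return token[len(key) + 1 :]
    return None


def read_fasta(
    path: str | Path,
    label: int | None = None,
    label_rule: Callable[[SeqRecord], int] | None = None,
    on_n: str = "warn",
) -> list[DnaRecord]:
    """Read labeled windows from a FASTA file.

    Labels are resolved, in order of precedence, by the explicit file-role
    ``label`` (two-file layouts: one positives file, one negatives file), a
    caller-supplied ``label_rule``, a ``label=<0|1>`` description token, or a
    case-insensitive ``pos``/``neg`` identifier prefix.

    Records containing N are dropped; ``on_n`` controls whether the count is
    logged (``"warn"``, default), suppressed (``"silent"``), or fatal
    (``"error"``).
    """
    path = Path(path)
    text_head = path.read_text()[:1024].lstrip()
    if text_head and not text_head.startswith(">"):
        raise ValueError(f"{path}: not FASTA (first record does not start with '>')")
    if on_n not in ("warn", "silent", "error"):
        raise ValueError("on_n must be 'warn', 'silent' or 'error'")

    out: list[DnaRecord] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET - {"N"}
        if bad:
            raise ValueError(
                f"record {rec.id!r}: characters {sorted(bad)} outside "
                "{A,C,G,T,N}"
            )
        if "N" in seq:
            if on_n == "error":
                raise ValueError(f"record {rec.id!r} contains N")
            n_dropped += 1
            continue
        if label is not None:
            y = label
        elif label_rule is not None:
            y = label_rule(rec)
        else:
            inferred = _label_from_record(rec)
            if inferred is None:
                raise ValueError(
                    f"record {rec.id!r}: cannot infer label (no label= token, "
                    "no pos/neg ID prefix); pass label= or label_rule="
                )
            y = inferred
        out.append(
            DnaRecord(
                identifier=rec.id,
                sequence=seq,
                label=y,
                species=_tag_from_description(rec, "species"),
                mod_type=_tag_from_description(rec, "mod_type"),
            )
        )
    if n_dropped and on_n == "warn":
        log.warning("%s: dropped %d record(s) containing N", path, n_dropped)
    return out


def write_fasta(records: Sequence[DnaRecord], path: str | Path) -> None:
    """Write records as FASTA with a ``label=`` description token."""
    seq_records = []
    for r in records:
        desc = f"label={r.label}"
        if r.species:
            desc += f" species={r.species}"
        if r.mod_type:
            desc += f" mod_type={r.mod_type}"
        seq_records.append(SeqRecord(Seq(r.sequence), id=r.identifier, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Delimited text


def read_table(path: str | Path) -> list[DnaRecord]:
    """Read windows from delimited text (tab or comma).

    Accepts two columns (sequence, label) or three (identifier, sequence,
    label); a header row is detected and skipped.  Identifiers default to row
    numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, found {df.shape[1]}")
    first_label = str(df.iloc[0, -1]).strip()
    if first_label not in ("0", "1"):
        try:
            float(first_label)
        except ValueError:
            df = df.iloc[1:].reset_index(drop=True)  # header row
        else:
            raise ValueError(f"{path}: row 1 label {first_label!r} is not 0 or 1")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        cells = [str(c).strip() for c in row]
        if len(cells) == 2:
            ident, seq, lab = f"row_{row_no}", cells[0], cells[1]
        else:
            ident, seq, lab = cells
        if lab not in ("0", "1"):
            raise ValueError(f"{path}: row {row_no} label {lab!r} is not 0 or 1")
        out.append(DnaRecord(identifier=ident, sequence=seq, label=int(lab)))
    return out


def write_table(records: Sequence[DnaRecord], path: str | Path) -> None:
    """Write records as delimited text (comma for .csv, tab otherwise)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        {
            "identifier": [r.identifier for r in records],
            "sequence": [r.sequence for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Splitting


def _largest_remainder(n: int, fractions: np.ndarray) -> list[int]:
    """Apportion n into parts by largest remainder; ties go to later parts."""
    exact = fractions * n
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    leftover = n - int(sizes.sum())
    # sort by remainder descending, ties broken toward the later part
    order = sorted(range(len(fractions)), key=lambda p: (-remainder[p], -p))
    for p in order[:leftover]:
        sizes[p] += 1
    return sizes.tolist()


def split_dataset(
    records: Sequence[DnaRecord],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratified: bool = True,
) -> DatasetSplit:
    """Partition records into train/validation/test parts.

    Sizes follow largest-remainder rounding of ``fractions``; the split is
    deterministic given ``seed``.  With ``stratified`` (default) each class
    is apportioned separately so part class ratios match the input within one
    record per class.  Parts preserve the input record order.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or (fr < 0).any():
        raise ValueError("fractions must be three non-negative numbers")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fr.sum()!r}, not 1")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")

    rng = np.random.default_rng(seed)
    labels = np.array([r.label for r in records])
    assignments = np.empty(n, dtype=int)

    if stratified:
        groups = [np.flatnonzero(labels == c) for c in (0, 1)]
        groups = [g for g in groups if g.size]
    else:
        groups = [np.arange(n)]
    for g in groups:
        perm = g[rng.permutation(g.size)]
        sizes = _largest_remainder(g.size, fr)
        bounds = np.cumsum([0] + sizes)
        for part in range(3):
            assignments[perm[bounds[part] : bounds[part + 1]]] = part

    parts: list[tuple[DnaRecord, ...]] = []
    for part in range(3):
        idx = np.flatnonzero(assignments == part)
        parts.append(tuple(records[i] for i in idx))
        if not idx.size:
            log.warning("split part %d is empty (n=%d, fractions=%s)", part, n, fractions)
    return DatasetSplit(parts[0], parts[1], parts[2], tuple(fr.tolist()))


# ---------------------------------------------------------------------------
# Synthetic data


def generate_synthetic(config: SyntheticConfig) -> list[DnaRecord]:
    """Generate a motif-planted synthetic dataset (positives, then negatives)."""
    rng = np.random.default_rng(config.seed)
    L, comp = config.length, np.asarray(config.base_composition, dtype=float)
    motif = np.array(list(config.motif))
    start = config.motif_start
    out: list[DnaRecord] = []

    for i in range(config.n_pos):
        window = rng.choice(_BASES, size=L, p=comp)
        window[start : start + motif.size] = motif
        for j in range(motif.size):
            if rng.random() < config.mutation_rate:
                alternatives = _BASES[_BASES != window[start + j]]
                window[start + j] = alternatives[rng.integers(3)]
        out.append(DnaRecord(f"pos_{i:05d}", "".join(window), 1))
    for i in range(config.n_neg):
        window = rng.choice(_BASES, size=L, p=comp)
        out.append(DnaRecord(f"neg_{i:05d}", "".join(window), 0))
    return out
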