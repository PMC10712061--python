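"""End-to-end orchestration: encode, swarm-train, evaluate, ablate, transfer.

Training encodes the windows under the configured scheme, z-scores each
channel with statistics fitted on the training part only, and hands the
packed conv + LSTM + head parameter vector to the chaotic swarm optimizer
with mean binary cross-entropy on the training part as fitness.  Each of
``n_restarts`` independent swarms contributes one member (its incumbent
checkpoint with the best validation accuracy, ties broken by lower training
loss); the model predicts with the average probability of the members, a
score ensemble that damps the run-to-run variance of gradient-free
training.  Validation labels enter only through checkpoint/member ranking;
test data never influences training.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import capso, network
from .capso import SwarmConfig
from .encodings import CHANNELS, encode_dataset
from .evaluation import EvaluationReport, evaluate
from .network import NetworkConfig, forward_batch, parameter_count, unpack_parameters
from .sequence_io import DnaRecord, split_dataset

__all__ = [
    "ExperimentConfig",
    "TrainedModel",
    "CrossSpeciesResult",
    "train",
    "test",
    "predict_scores",
    "encoding_ablation",
    "cross_species",
]

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: above this packed-vector length, swarm search is warned to degrade
DIMENSION_WARNING = 20_000


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: encoding scheme, architecture, swarm, split.

    ``n_restarts`` independent swarm runs (seeds derived deterministically
    from the swarm seed) each contribute one member to a score-averaging
    ensemble; swarm search from a random population is noisy enough that
    the restarts are part of the training procedure, not an extra.
    """

    scheme: str = "code9"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    swarm: SwarmConfig = field(
        default_factory=lambda: SwarmConfig(n_iterations=350, r_scale=0.1,
                                            r_decay=0.993)
    )
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    split_seed: int = 0
    n_restarts: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in CHANNELS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.network.scheme != self.scheme:
            object.__setattr__(
                self, "network", dataclasses.replace(self.network, scheme=self.scheme)
            )

    def restart_seeds(self) -> tuple[int, ...]:
        base = self.swarm.rng_seed
        return tuple((base + k * 1_000_003) % 2_147_483_647 for k in range(self.n_restarts))


@dataclass(frozen=True)
class TrainedModel:
    """A trained Con-LSTM classifier with its standardization statistics.

    ``members`` holds one packed parameter vector per restart, ranked by
    validation accuracy; the model's score is the mean probability over the
    members.  ``packed`` is the top-ranked member, usable as a single
    network.
    """

    config: ExperimentConfig
    seq_length: int
    channel_mean: np.ndarray  # (channels,)
    channel_std: np.ndarray  # (channels,)
    members: np.ndarray  # (n_members, dim) packed vectors, best first
    train_loss: float
    trace: tuple[float, ...]
    validation_report: EvaluationReport | None = None

    @property
    def packed(self) -> np.ndarray:
        return self.members[0]

    @property
    def parameters(self):
        return unpack_parameters(self.packed, self.config.network)

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "scheme": self.config.scheme,
            "network": dataclasses.asdict(self.config.network),
            "swarm": dataclasses.asdict(self.config.swarm),
            "fractions": list(self.config.fractions),
            "split_seed": self.config.split_seed,
            "n_restarts": self.config.n_restarts,
            "seq_length": self.seq_length,
            "train_loss": self.train_loss,
            "validation_report": (
                self.validation_report.to_dict() if self.validation_report else None
            ),
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            channel_mean=self.channel_mean,
            channel_std=self.channel_std,
            members=self.members,
            trace=np.asarray(self.trace),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as blob:
            meta = json.loads(str(blob["meta"]))
            if meta["format_version"] != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format version {meta['format_version']}"
                )
            swarm_kwargs = dict(meta["swarm"])
            if swarm_kwargs.get("chaos_seeds") is not None:
                swarm_kwargs["chaos_seeds"] = tuple(swarm_kwargs["chaos_seeds"])
            config = ExperimentConfig(
                scheme=meta["scheme"],
                network=NetworkConfig(**meta["network"]),
                swarm=SwarmConfig(**swarm_kwargs),
                fractions=tuple(meta["fractions"]),
                split_seed=meta["split_seed"],
                n_restarts=meta.get("n_restarts", 1),
            )
            return cls(
                config=config,
                seq_length=int(meta["seq_length"]),
                channel_mean=blob["channel_mean"].copy(),
                channel_std=blob["channel_std"].copy(),
                members=blob["members"].copy(),
                train_loss=float(meta["train_loss"]),
                trace=tuple(blob["trace"].tolist()),
                validation_report=None,
            )

    def save_trace(self, path: str | Path) -> None:
        pd.DataFrame(
            {"iteration": range(len(self.trace)), "best_fitness": self.trace}
        ).to_csv(path, index=False)


def _validate_records(records: Sequence[DnaRecord], part: str) -> np.ndarray:
    if not records:
        raise ValueError(f"{part} part is empty")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{part} part has mixed sequence lengths {sorted(lengths)}")
    labels = np.array([r.label for r in records])
    return labels


def _standardize(X: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (X - mean[None, :, None]) / std[None, :, None]


def _bce(labels: np.ndarray, probs: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def train(
    train_records: Sequence[DnaRecord],
    validation_records: Sequence[DnaRecord],
    config: ExperimentConfig | None = None,
) -> TrainedModel:
    """Swarm-train the Con-LSTM on the training part.

    Deterministic given the seeds inside ``config``.  Raises if either part
    is empty, single-class (training), or of mixed sequence length.
    """
    config = config or ExperimentConfig()
    y_train = _validate_records(train_records, "training")
    y_val = _validate_records(validation_records, "validation")
    if len(set(y_train)) < 2:
        raise ValueError("training part must contain both classes")
    if len(train_records[0]) != len(validation_records[0]):
        raise ValueError("training and validation sequence lengths differ")

    X_train = encode_dataset(train_records, config.scheme)
    X_val = encode_dataset(validation_records, config.scheme)
    mean = X_train.mean(axis=(0, 2))
    std = np.maximum(X_train.std(axis=(0, 2)), 1e-8)
    Xs = _standardize(X_train, mean, std)
    Xv = _standardize(X_val, mean, std)

    net = config.network
    dim = parameter_count(net)
    if dim > DIMENSION_WARNING:
        log.warning("packed parameter vector has %d entries; swarm search "
                    "degrades in high dimension", dim)
    log.info("training scheme=%s dim=%d n_train=%d n_val=%d restarts=%d",
             config.scheme, dim, len(train_records), len(validation_records),
             config.n_restarts)

    def fitness(vector: np.ndarray) -> float:
        conv, lstm, head = unpack_parameters(vector, net)
        return _bce(y_train, forward_batch(Xs, conv, lstm, head, net.pool_width))

    def validation_accuracy(vector: np.ndarray) -> float:
        conv, lstm, head = unpack_parameters(vector, net)
        probs = forward_batch(Xv, conv, lstm, head, net.pool_width)
        return float(np.mean((probs >= net.threshold) == (y_val == 1)))

    # each restart contributes its incumbent with the best validation
    # accuracy (ties -> lower train loss) as one ensemble member
    members = []
    for restart, seed in enumerate(config.restart_seeds()):
        swarm = dataclasses.replace(config.swarm, rng_seed=seed)
        result = capso.optimize(fitness, dim, swarm)
        best = None
        for iteration, loss, vector in result.improvements:
            key = (-validation_accuracy(vector), loss, iteration)
            if best is None or key < best[0]:
                best = (key, vector, loss)
        (neg_acc, loss, _), vector, train_loss = best
        members.append((neg_acc, loss, restart, vector, tuple(result.trace)))
    members.sort(key=lambda m: (m[0], m[1], m[2]))
    # a restart that collapsed (validation accuracy far below the best
    # member's) would poison the average; keep members within 10 points
    best_acc = -members[0][0]
    kept = [m for m in members if -m[0] >= best_acc - 0.10]
    if len(kept) < len(members):
        log.info("dropping %d of %d restart member(s) below the validation "
                 "sanity margin", len(members) - len(kept), len(members))
    members = kept
    stacked = np.stack([m[3] for m in members])

    model = TrainedModel(
        config=config,
        seq_length=len(train_records[0]),
        channel_mean=mean,
        channel_std=std,
        members=stacked,
        train_loss=members[0][1],
        trace=members[0][4],
        validation_report=None,
    )
    val_probs = _ensemble_probs(stacked, Xv, net)
    val_report = evaluate(y_val, val_probs, net.threshold, tag=config.scheme)
    return dataclasses.replace(model, validation_report=val_report)


def _ensemble_probs(members: np.ndarray, X: np.ndarray, net: NetworkConfig) -> np.ndarray:
    probs = [
        forward_batch(X, *unpack_parameters(vector, net), net.pool_width)
        for vector in members
    ]
    return np.mean(probs, axis=0)


def predict_scores(model: TrainedModel, records: Sequence[DnaRecord]) -> np.ndarray:
    """Class-1 probabilities: mean over ensemble members' forward passes."""
    _validate_records(records, "prediction")
    if len(records[0]) != model.seq_length:
        raise ValueError(
            f"records have length {len(records[0])}, model was trained on "
            f"{model.seq_length}"
        )
    X = encode_dataset(records, model.config.scheme)
    Xs = _standardize(X, model.channel_mean, model.channel_std)
    return _ensemble_probs(model.members, Xs, model.config.network)


def test(
    model: TrainedModel, records: Sequence[DnaRecord], tag: str | None = None
) -> EvaluationReport:
    """Evaluate the model on held-out records at its stored threshold."""
    labels = _validate_records(records, "test")
    scores = predict_scores(model, records)
    return evaluate(labels, scores, model.config.network.threshold,
                    tag=tag or model.config.scheme)


def encoding_ablation(
    records: Sequence[DnaRecord],
    schemes: Sequence[str] = ("code1", "code9"),
    config: ExperimentConfig | None = None,
) -> dict[str, EvaluationReport]:
    """Train/test once per scheme on one shared split.

    The split (and every seed) is identical across schemes, so differences in
    the reports reflect the encodings alone.
    """
    config = config or ExperimentConfig()
    for scheme in schemes:
        if scheme not in CHANNELS:
            raise ValueError(f"unknown scheme {scheme!r}")
    split = split_dataset(records, config.fractions, seed=config.split_seed)
    out: dict[str, EvaluationReport] = {}
    for scheme in schemes:
        scheme_config = dataclasses.replace(config, scheme=scheme)
        model = train(split.train, split.validation, scheme_config)
        out[scheme] = test(model, split.test, tag=scheme)
    return out


@dataclass(frozen=True)
class CrossSpeciesResult:
    """k x k matrix of reports keyed by (training dataset, testing dataset)."""

    tags: tuple[str, ...]
    reports: Mapping[tuple[str, str], EvaluationReport]

    def metric_frame(self, metric: str = "auc") -> pd.DataFrame:
        """One metric as a k x k table; rows = training tag, columns = testing tag."""
        return pd.DataFrame(
            [
                [getattr(self.reports[(ti, tj)], metric) for tj in self.tags]
                for ti in self.tags
            ],
            index=list(self.tags),
            columns=list(self.tags),
        )

    def to_csv(self, directory: str | Path,
               metrics: Sequence[str] = ("sn_pct", "sp_pct", "acc_pct", "mcc", "auc")) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for metric in metrics:
            self.metric_frame(metric).to_csv(directory / f"cross_species_{metric}.csv")


def cross_species(
    datasets: Mapping[str, Sequence[DnaRecord]],
    config: ExperimentConfig | None = None,
) -> CrossSpeciesResult:
    """Train one model per dataset; evaluate each on every dataset's test part.

    Every dataset is split with the shared fractions and seed; a model trained
    on dataset i (its train part, checkpoint-selected on its validation part)
    is evaluated on the test part of every dataset j, the diagonal being the
    ordinary within-dataset held-out evaluation.  Degenerate folds are flagged
    in their reports, never fatal.
    """
    config = config or ExperimentConfig()
    if len(datasets) < 2:
        raise ValueError("cross-species validation needs at least 2 datasets")
    lengths = {len(r) for records in datasets.values() for r in records}
    if len(lengths) != 1:
        raise ValueError(f"datasets have mixed sequence lengths {sorted(lengths)}")

    tags = tuple(datasets)
    splits = {
        tag: split_dataset(datasets[tag], config.fractions, seed=config.split_seed)
        for tag in tags
    }
    reports: dict[tuple[str, str], EvaluationReport] = {}
    for ti in tags:
        model = train(splits[ti].train, splits[ti].validation, config)
        for tj in tags:
            reports[(ti, tj)] = test(model, splits[tj].test, tag=f"{ti}->{tj}")
    return CrossSpeciesResult(tags=tags, reports=reports)
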