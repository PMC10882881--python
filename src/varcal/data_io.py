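"""Typed containers for scores and labels, plus table readers/writers.

The toolkit operates on abstract (score, label) pairs: ``LabeledScores`` holds
one real-valued predictor score and one binary pathogenicity label per item,
``ContinuousPairs`` holds predicted/observed continuous assay values. Scores
are normalized at load time so that, internally, higher always means "more
pathogenic" (``lower_is_positive`` inputs are sign-flipped once).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LabeledScores",
    "ContinuousPairs",
    "AnalysisConfig",
    "LoadReport",
    "read_scores",
    "read_continuous",
    "write_scores",
    "write_continuous",
    "run_report",
    "DEFAULT_LABEL_MAP",
]

#: Accepted label spellings (case-insensitive) mapped to {0, 1}.
DEFAULT_LABEL_MAP: Mapping[str, int] = {
    "0": 0,
    "1": 1,
    "benign": 0,
    "pathogenic": 1,
    "negative": 0,
    "positive": 1,
}

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class LoadReport:
    """Summary of what a reader kept and dropped."""

    n_read: int
    n_kept: int
    n_dropped: int
    dropped_rows: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.n_kept} kept, {self.n_dropped} dropped of {self.n_read} rows"


@dataclass(frozen=True)
class LabeledScores:
    """Per-item predictor score with a binary pathogenicity label.

    Parameters
    ----------
    item_ids
        Opaque unique identifiers, one per item.
    scores
        Real-valued predictor scores, already oriented so that higher means
        more likely pathogenic.
    labels
        Binary labels, 1 = pathogenic/positive, 0 = benign/negative.
    flipped
        True when the input orientation was ``lower_is_positive`` and scores
        were negated at load. ``to_original_scale`` undoes the flip.
    """

    item_ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    flipped: bool = False
    load_report: Optional[LoadReport] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.item_ids, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=np.int8)
        if not (len(ids) == len(scores) == len(labels)):
            raise ValueError("item_ids, scores and labels must have equal length")
        if len(ids) == 0:
            raise ValueError("no usable items")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        object.__setattr__(self, "item_ids", ids)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    @property
    def test_prior(self) -> float:
        """Observed positive fraction alpha_D of this set."""
        return self.n_positive / len(self)

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError(
                "both label classes must be present "
                f"(have {self.n_positive} positive, {self.n_negative} negative)"
            )

    def flip_orientation(self) -> "LabeledScores":
        """Negate scores and toggle the flipped flag (an involution)."""
        return LabeledScores(self.item_ids, -self.scores, self.labels,
                             flipped=not self.flipped)

    def to_original_scale(self, value: float) -> float:
        """Map a normalized score/threshold back to the as-loaded scale."""
        return -value if self.flipped else value

    def take(self, indices: np.ndarray) -> "LabeledScores":
        """Row subset/resample; item ids are re-keyed to stay unique."""
        idx = np.asarray(indices)
        ids = np.array([f"r{k}" for k in range(len(idx))], dtype=object)
        return LabeledScores(ids, self.scores[idx], self.labels[idx],
                             flipped=self.flipped)


@dataclass(frozen=True)
class ContinuousPairs:
    """Per-item predicted and observed continuous phenotype values."""

    item_ids: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray
    load_report: Optional[LoadReport] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.item_ids, dtype=object)
        pred = np.asarray(self.predicted, dtype=float)
        obs = np.asarray(self.observed, dtype=float)
        if not (len(ids) == len(pred) == len(obs)):
            raise ValueError("item_ids, predicted and observed must have equal length")
        if len(ids) == 0:
            raise ValueError("no usable items")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
            raise ValueError("values must be finite")
        object.__setattr__(self, "item_ids", ids)
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "observed", obs)

    def __len__(self) -> int:
        return len(self.predicted)

    def take(self, indices: np.ndarray) -> "ContinuousPairs":
        idx = np.asarray(indices)
        ids = np.array([f"r{k}" for k in range(len(idx))], dtype=object)
        return ContinuousPairs(ids, self.predicted[idx], self.observed[idx])


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across the analysis stages.

    ``target_prior`` is the reference-population prior probability of
    pathogenicity alpha; ``test_prior_override`` replaces the observed
    positive fraction alpha_D when the test set is known to be unrepresentative.
    ``evidence_constant`` is the likelihood ratio c carried by one Very Strong
    line of evidence (351 pairs with the default prior 0.10; 8511 with 0.01),
    or the string ``"solve"`` to derive c from a user-supplied rule list.
    """

    target_prior: float = 0.10
    test_prior_override: Optional[float] = None
    evidence_constant: Union[float, str] = 351.0
    truncation_fpr: float = 0.2
    window_fraction: float = 0.05
    window_min_fraction: float = 0.10
    window_max_count: int = 50
    bootstrap_iterations: int = 1000
    ci_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prior < 1.0:
            raise ValueError("target_prior must be in (0, 1)")
        if self.test_prior_override is not None and not 0.0 < self.test_prior_override < 1.0:
            raise ValueError("test_prior_override must be in (0, 1)")
        for name in ("truncation_fpr", "window_fraction", "window_min_fraction", "ci_level"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if isinstance(self.evidence_constant, str):
            if self.evidence_constant != "solve":
                raise ValueError("evidence_constant must be a number > 1 or 'solve'")
        elif self.evidence_constant <= 1.0:
            raise ValueError("evidence_constant must be > 1")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        if self.window_max_count < 1:
            raise ValueError("window_max_count must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _read_table(path: Union[str, Path], fmt: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError("format must be 'tsv' or 'csv'")
    sep = "\t" if fmt == "tsv" else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, names: Sequence[str], path) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; have {list(df.columns)}")


def _parse_label(raw: str, row: int, label_map: Mapping[str, int], path) -> Optional[int]:
    text = raw.strip()
    if text == "":
        return None
    key = text.lower()
    if key not in label_map:
        raise ValueError(f"{path} row {row}: unparseable label {raw!r}")
    return label_map[key]


def read_scores(
    path: Union[str, Path],
    *,
    format: Optional[str] = None,
    score_column: str = "score",
    label_column: str = "label",
    id_column: Optional[str] = None,
    orientation: str = "higher_is_positive",
    label_map: Optional[Mapping[str, int]] = None,
) -> LabeledScores:
    """Read (item, score, label) rows from a TSV/CSV file.

    Rows with a missing score or label are dropped and counted in the
    attached :class:`LoadReport`; an unparseable (non-empty) label is an
    error naming the offending row.
    """
    if orientation not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError("orientation must be 'higher_is_positive' or 'lower_is_positive'")
    lmap = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    df = _read_table(path, format)
    _require_columns(df, [score_column, label_column], path)

    ids, scores, labels, dropped = [], [], [], []
    for row in range(1, len(df) + 1):
        raw_score = str(df.iloc[row - 1][score_column]).strip()
        label = _parse_label(str(df.iloc[row - 1][label_column]), row, lmap, path)
        if raw_score == "" or label is None:
            dropped.append(row)
            continue
        try:
            score = float(raw_score)
        except ValueError as exc:
            raise ValueError(f"{path} row {row}: unparseable score {raw_score!r}") from exc
        item = str(df.iloc[row - 1][id_column]) if id_column else f"item{row}"
        ids.append(item)
        scores.append(score)
        labels.append(label)

    if not ids:
        raise ValueError(f"{path}: zero usable rows")
    report = LoadReport(n_read=len(df), n_kept=len(ids), n_dropped=len(dropped),
                        dropped_rows=tuple(dropped))
    scores_arr = np.asarray(scores, dtype=float)
    flipped = orientation == "lower_is_positive"
    if flipped:
        scores_arr = -scores_arr
    return LabeledScores(np.asarray(ids, dtype=object), scores_arr,
                         np.asarray(labels, dtype=np.int8),
                         flipped=flipped, load_report=report)


def read_continuous(
    path: Union[str, Path],
    *,
    format: Optional[str] = None,
    predicted_column: str = "predicted",
    observed_column: str = "observed",
    id_column: Optional[str] = None,
) -> ContinuousPairs:
    """Read (item, predicted, observed) rows from a TSV/CSV file."""
    df = _read_table(path, format)
    _require_columns(df, [predicted_column, observed_column], path)

    ids, pred, obs, dropped = [], [], [], []
    for row in range(1, len(df) + 1):
        rp = str(df.iloc[row - 1][predicted_column]).strip()
        ro = str(df.iloc[row - 1][observed_column]).strip()
        if rp == "" or ro == "":
            dropped.append(row)
            continue
        try:
            p, o = float(rp), float(ro)
        except ValueError as exc:
            raise ValueError(f"{path} row {row}: non-numeric value") from exc
        ids.append(str(df.iloc[row - 1][id_column]) if id_column else f"item{row}")
        pred.append(p)
        obs.append(o)

    if not ids:
        raise ValueError(f"{path}: zero usable rows")
    report = LoadReport(n_read=len(df), n_kept=len(ids), n_dropped=len(dropped),
                        dropped_rows=tuple(dropped))
    return ContinuousPairs(np.asarray(ids, dtype=object),
                           np.asarray(pred, dtype=float),
                           np.asarray(obs, dtype=float),
                           load_report=report)


def write_scores(scores: LabeledScores, path: Union[str, Path],
                 *, format: str = "tsv") -> None:
    """Write a LabeledScores table that read_scores round-trips bit-exactly.

    Scores are written on the original (as-loaded) scale with 17 significant
    digits so the text form preserves the IEEE double exactly.
    """
    sep = "\t" if format == "tsv" else ","
    out = scores.scores if not scores.flipped else -scores.scores
    with open(path, "w") as fh:
        fh.write(sep.join(["item_id", "score", "label"]) + "\n")
        for i, s, y in zip(scores.item_ids, out, scores.labels):
            fh.write(sep.join([str(i), _FLOAT_FMT % s, str(int(y))]) + "\n")


def write_continuous(pairs: ContinuousPairs, path: Union[str, Path],
                     *, format: str = "tsv") -> None:
    sep = "\t" if format == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(sep.join(["item_id", "predicted", "observed"]) + "\n")
        for i, p, o in zip(pairs.item_ids, pairs.predicted, pairs.observed):
            fh.write(sep.join([str(i), _FLOAT_FMT % p, _FLOAT_FMT % o]) + "\n")


def run_report(config: AnalysisConfig,
               data: Union[LabeledScores, ContinuousPairs]) -> dict:
    """Full analysis report for a score set; see :mod:`varcal.report`."""
    from . import report as _report  # local import avoids a cycle

    return _report.run_report(config, data)
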