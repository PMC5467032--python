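"""Contest-style scoring of association submissions.

A submission is an M x P matrix of Wald chi-square statistics flattened into
a list ordered by decreasing significance.  Scoring proceeds in three steps:

* ``accuracy_score``: walk the submitted list in rank order; rank ``i`` is
  correct when the submitted statistic matches the reference statistic at the
  same rank within a relative tolerance (0.1% by default); the score is the
  number of correct entries *before the first mistake*.
* ``raw_score = accuracy / (1 + max(time_spent, 100 ms) / time_limit)`` with
  ``time_limit`` = 100 ms, so the divisor is at least 2.  (Prose descriptions
  of this penalty as ranging over (1, 2] conflict with the formula's 100 ms
  floor; the formula as printed is what is implemented, and ``time_limit_ms``
  is exposed for sensitivity analysis.)
* ``scaled_score = raw / max(P, best_raw)`` where ``best_raw`` is the best
  raw score achieved on the test case; the ``max`` guards against score
  inflation on very hard cases.  A contest total is the sum of scaled scores
  over cases.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Submission",
    "ScoreReport",
    "accuracy_score",
    "raw_score",
    "scaled_score",
    "score_submission",
    "read_submission_tsv",
    "write_score_report",
]

DEFAULT_REL_TOL = 0.001
DEFAULT_TIME_LIMIT_MS = 100.0


@dataclass
class Submission:
    """A ranked list of (marker, phenotype, z2) plus the wall-clock spent."""

    ranked_z: list[tuple[int, int, float]]
    time_spent_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.time_spent_ms < 0:
            raise ValueError("time_spent_ms must be >= 0")

    @property
    def z2(self) -> np.ndarray:
        return np.array([t[2] for t in self.ranked_z], dtype=np.float64)


@dataclass
class ScoreReport:
    """Accuracy, raw and scaled scores for one submission on one test case."""

    accuracy: int
    raw: float
    scaled: float
    best_raw: float
    p: int
    time_limit_ms: float = DEFAULT_TIME_LIMIT_MS

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def accuracy_score(
    submitted_z2,
    reference_z2,
    rel_tol: float = DEFAULT_REL_TOL,
    match: str = "rank",
) -> int:
    """Number of correct statistics before the first mistake.

    ``match="rank"`` (default): the submitted statistic at rank ``i`` must
    equal the reference statistic at rank ``i`` within ``rel_tol`` relative
    tolerance.  ``match="membership"`` is a sensitivity variant where rank
    ``i`` is correct if the submitted value matches *any* reference value
    within tolerance.
    """
    sub = np.asarray(submitted_z2, dtype=np.float64).ravel()
    ref = np.asarray(reference_z2, dtype=np.float64).ravel()
    if match not in ("rank", "membership"):
        raise ValueError(f"unknown match mode {match!r}")
    count = 0
    for i, z in enumerate(sub):
        if match == "rank":
            ok = i < ref.size and abs(z - ref[i]) <= rel_tol * abs(ref[i])
        else:
            ok = bool(np.any(np.abs(z - ref) <= rel_tol * np.abs(ref)))
        if not ok:
            break
        count += 1
    return count


def raw_score(
    accuracy: float,
    time_spent_ms: float,
    time_limit_ms: float = DEFAULT_TIME_LIMIT_MS,
) -> float:
    """``accuracy / (1 + max(time_spent, 100 ms) / time_limit)``."""
    if accuracy < 0 or time_spent_ms < 0 or time_limit_ms <= 0:
        raise ValueError("scores and times must be non-negative (limit positive)")
    return accuracy / (1.0 + max(time_spent_ms, 100.0) / time_limit_ms)


def scaled_score(raw: float, best_raw: float, p: int) -> float:
    """``raw / max(P, best_raw)``; the best submission scores 1 when
    ``best_raw >= P``."""
    if p <= 0:
        raise ValueError("P must be a positive phenotype count")
    if raw < 0 or best_raw < 0:
        raise ValueError("raw scores must be non-negative")
    return raw / max(float(p), best_raw)


def score_submission(
    submission: Submission,
    reference_z2,
    p: int,
    best_raw: float | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    time_limit_ms: float = DEFAULT_TIME_LIMIT_MS,
    match: str = "rank",
) -> ScoreReport:
    """Score one submission against a ranked reference.

    ``reference_z2`` must already be in decreasing order (the pipeline's
    deterministic tie rule).  When ``best_raw`` is None the submission is
    treated as the best on the case.
    """
    acc = accuracy_score(submission.z2, reference_z2, rel_tol=rel_tol, match=match)
    raw = raw_score(acc, submission.time_spent_ms, time_limit_ms)
    best = raw if best_raw is None else float(best_raw)
    return ScoreReport(
        accuracy=acc,
        raw=raw,
        scaled=scaled_score(raw, best, p),
        best_raw=best,
        p=p,
        time_limit_ms=time_limit_ms,
    )


def read_submission_tsv(path, time_spent_ms: float = 0.0) -> Submission:
    """Read a ranked submission TSV with columns marker_id, phenotype_index, z2."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["marker", "pheno", "z2"],
                         comment="#")
    except pd.errors.EmptyDataError:
        return Submission(ranked_z=[], time_spent_ms=time_spent_ms)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed submission TSV ({exc})") from exc
    df["z2"] = pd.to_numeric(df["z2"], errors="coerce")
    if df["z2"].isna().any():
        bad = int(df.index[df["z2"].isna()][0]) + 1
        raise ValueError(f"{path}: line {bad}: z2 is not a number")
    ranked = list(df.itertuples(index=False, name=None))
    return Submission(ranked_z=ranked, time_spent_ms=time_spent_ms)


def write_score_report(report: ScoreReport, path) -> None:
    Path(path).write_text(report.to_json() + "\n")
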