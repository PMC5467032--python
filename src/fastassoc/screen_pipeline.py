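"""One-step screening, ranking, chunked scans, and the two-pass association pipeline.

The pipeline reproduces the fast GWAS workflow:

1. *Screen* (vectorized): for each phenotype, a single Newton update from the
   covariate-only warm start gives every marker an approximate Wald ``z2``.
   Because the warm start is the converged covariate-only fit, the update has
   closed form ``z2 = s^2 / schur`` with score ``s = g'(y - mu)`` and Schur
   complement ``schur = g'Wg - b'A^-1 b`` — all markers share ``mu``, ``W``
   and the Cholesky factor of ``A = Xc'WXc``, so the screen is a handful of
   BLAS-3 products per block of markers.
2. *Fast pass*: survivors of the screen are refit with an iteration-limited
   warm-started Newton solve.
3. *Exact pass*: markers retained by the fast pass are refit to full
   convergence with per-marker exclusion of subjects missing that genotype,
   and reported in PLINK ``.assoc.logistic`` format.

Chunked execution partitions the per-marker fitting work into contiguous
ranges whose merged output is bitwise identical to an unchunked run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special

from fastassoc.logit_core import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    AssociationResult,
    FitState,
    RegressionDesign,
    STATUS_OK,
    STATUS_SEPARATION,
    chisq1_p,
    fit_covariate_only,
    fit_marker,
)
from fastassoc.plink_io import MISSING, GenotypeStudy, to_design_matrix

__all__ = [
    "ScreenConfig",
    "RankedResults",
    "AssociationRun",
    "one_step_screen",
    "rank_results",
    "chunk_markers",
    "exact_scan",
    "fast_scan",
    "two_pass",
    "run_association",
    "pipeline_summary",
    "write_assoc_logistic",
    "write_screen_file",
]

#: Wald critical value for the 95% CI on the log-odds scale (PLINK's constant)
CI_Z = 1.959964

ASSOC_COLUMNS = ["CHR", "SNP", "BP", "A1", "TEST", "NMISS", "OR", "SE", "L95", "U95", "STAT", "P"]

#: marker block width for the vectorized screen (absolute-index aligned)
_SCREEN_BLOCK = 4096


@dataclass
class ScreenConfig:
    """Configuration of the screening/two-pass association run.

    ``screen_p_cutoff`` is the user's reporting threshold (markers with final
    p above it are still emitted, flagged); ``screen_margin`` relaxes the
    cutoff multiplicatively at the screening stages so borderline markers are
    not lost to approximation error; ``fast_iters`` is the Newton budget after
    the single screening step for markers that survive it.
    """

    screen_p_cutoff: float = 1e-3
    screen_margin: float = 10.0
    n_chunks: int = 1
    mode: str = "two_pass"
    fast_iters: int = 3
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    missing_policy: str = "error"
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.screen_p_cutoff <= 1.0):
            raise ValueError("screen_p_cutoff must be in (0, 1]")
        if self.screen_margin < 1.0:
            raise ValueError("screen_margin must be >= 1")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.mode not in ("fast", "exact", "two_pass"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fast_iters < 0:
            raise ValueError("fast_iters must be >= 0")

    @property
    def screen_gate(self) -> float:
        """Effective screening p-value threshold (cutoff x margin, capped at 1)."""
        return min(1.0, self.screen_p_cutoff * self.screen_margin)


@dataclass
class RankedResults:
    """A total order over marker x phenotype statistics, descending z2.

    Ties are broken by (marker_index, phenotype_index) ascending so the order
    is deterministic.
    """

    marker_index: np.ndarray
    phenotype_index: np.ndarray
    z2: np.ndarray

    def __len__(self) -> int:
        return self.z2.size


@dataclass
class AssociationRun:
    """Output of :func:`run_association`: the report table, the optional
    per-marker screen table, and run bookkeeping counts."""

    table: pd.DataFrame
    screen: Optional[pd.DataFrame]
    summary: dict
    results: list[AssociationResult] = field(repr=False, default_factory=list)


def chunk_markers(n_markers: int, n_chunks: int) -> list[tuple[int, int]]:
    """Partition ``[0, n_markers)`` into at most ``n_chunks`` contiguous,
    near-equal half-open ranges (sizes differ by <= 1; empty ranges dropped)."""
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    base, rem = divmod(n_markers, n_chunks)
    ranges = []
    start = 0
    for k in range(n_chunks):
        size = base + (1 if k < rem else 0)
        if size == 0:
            continue
        ranges.append((start, start + size))
        start += size
    return ranges


def one_step_screen(
    study: GenotypeStudy | np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    warm: FitState,
) -> np.ndarray:
    """Approximate Wald ``z2`` for every marker from one Newton update.

    ``covariates`` must include the leading intercept column and match
    ``warm.beta``.  At the converged covariate-only fit the covariate score
    vanishes, so the single update for marker ``g`` reduces to the score
    statistic ``z2 = (g'r)^2 / (g'Wg - b'A^-1 b)`` with ``r = y - mu`` and
    ``b = Xc'Wg``, shared ``mu``/``W`` across markers.  Monomorphic markers
    (and markers in the covariate span, where the Schur complement vanishes)
    get ``z2 = 0``.
    """
    G = study.dosage if isinstance(study, GenotypeStudy) else study
    y = np.asarray(y, dtype=np.float64).ravel()
    Xc = np.asarray(covariates, dtype=np.float64)
    n, m = G.shape
    if y.size != n or Xc.shape[0] != n:
        raise ValueError("y/covariates rows do not match the genotype matrix")
    if warm.beta.size != Xc.shape[1]:
        raise ValueError("warm.beta length does not match the covariate block")

    mu = special.expit(Xc @ warm.beta)
    w = mu * (1.0 - mu)
    r = y - mu
    A = (Xc * w[:, None]).T @ Xc
    cA = linalg.cho_factor(A, check_finite=False)

    z2 = np.empty(m)
    wXc = Xc * w[:, None]
    for start in range(0, m, _SCREEN_BLOCK):
        stop = min(start + _SCREEN_BLOCK, m)
        Gb = np.asarray(G[:, start:stop], dtype=np.float64)
        B = wXc.T @ Gb                                   # (k, mb)
        Q = linalg.cho_solve(cA, B, check_finite=False)
        c = w @ (Gb * Gb)
        schur = c - (B * Q).sum(axis=0)
        s = Gb.T @ r
        safe = schur > 1e-10 * np.maximum(c, 1.0)
        blk = np.zeros(stop - start)
        np.divide(s * s, schur, out=blk, where=safe)
        z2[start:stop] = np.where(safe, blk, 0.0)
    return z2


def rank_results(z2_matrix: np.ndarray) -> RankedResults:
    """Rank an M x P matrix of Wald statistics in decreasing order of ``z2``,
    ties broken by (marker_index, phenotype_index) ascending."""
    z2_matrix = np.atleast_2d(np.asarray(z2_matrix, dtype=np.float64))
    if not np.all(np.isfinite(z2_matrix)):
        raise ValueError("z2 matrix must be finite")
    m, p = z2_matrix.shape
    marker = np.repeat(np.arange(m), p)
    pheno = np.tile(np.arange(p), m)
    flat = z2_matrix.ravel()
    order = np.lexsort((pheno, marker, -flat))
    return RankedResults(
        marker_index=marker[order], phenotype_index=pheno[order], z2=flat[order]
    )


def _marker_fit(
    G: np.ndarray,
    j: int,
    y: np.ndarray,
    Xc: np.ndarray,
    warm: FitState,
    tol: float,
    max_iter: int,
    ridge: float,
    excluded: Optional[np.ndarray],
    phenotype_index: int,
) -> AssociationResult:
    """Fit marker ``j``, excluding the given subject rows (missing calls)."""
    g = np.asarray(G[:, j], dtype=np.float64)
    if excluded is not None and excluded.size:
        keep = np.ones(g.size, dtype=bool)
        keep[excluded] = False
        g, ys, Xcs = g[keep], y[keep], Xc[keep]
        design = RegressionDesign(y=ys, covariates=Xcs, marker=g)
    else:
        design = RegressionDesign(y=y, covariates=Xc, marker=g)
    return fit_marker(
        design,
        warm,
        tol=tol,
        max_iter=max_iter,
        ridge=ridge,
        marker_index=j,
        phenotype_index=phenotype_index,
    )


def exact_scan(
    study: GenotypeStudy | np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    warm: Optional[FitState] = None,
    marker_indices: Optional[Sequence[int]] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    ridge: float = 0.0,
    masks: Optional[dict[int, np.ndarray]] = None,
    phenotype_index: int = 0,
) -> list[AssociationResult]:
    """Full-convergence fit of each requested marker (all markers by default).

    ``covariates`` includes the intercept column; ``masks`` maps marker index
    to subject rows excluded from that marker's fit.
    """
    G = study.dosage if isinstance(study, GenotypeStudy) else study
    y = np.asarray(y, dtype=np.float64).ravel()
    Xc = np.asarray(covariates, dtype=np.float64)
    if warm is None:
        warm = fit_covariate_only(y, Xc, tol=tol, max_iter=max_iter, ridge=ridge)
    idx = range(G.shape[1]) if marker_indices is None else marker_indices
    masks = masks or {}
    return [
        _marker_fit(G, int(j), y, Xc, warm, tol, max_iter, ridge, masks.get(int(j)), phenotype_index)
        for j in idx
    ]


def fast_scan(
    study: GenotypeStudy | np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    warm: FitState,
    marker_indices: Optional[Sequence[int]] = None,
    fast_iters: int = 3,
    tol: float = DEFAULT_TOL,
    ridge: float = 0.0,
    phenotype_index: int = 0,
) -> list[AssociationResult]:
    """Iteration-limited warm-started fit: one screening step plus
    ``fast_iters`` further Newton iterations (assumes complete data)."""
    return exact_scan(
        study,
        y,
        covariates,
        warm=warm,
        marker_indices=marker_indices,
        tol=tol,
        max_iter=1 + fast_iters,
        ridge=ridge,
        phenotype_index=phenotype_index,
    )


def pipeline_summary(
    n_subjects: int, n_markers: int, n_phenotypes: int = 1, **counts
) -> dict:
    """Run bookkeeping: problem dimensions and derived totals.

    ``n_genotype_observations`` is the total number of genotype calls the scan
    touches (N x M); ``n_regressions`` is the number of marker-by-phenotype
    fits (M x P).
    """
    out = {
        "n_subjects": int(n_subjects),
        "n_markers": int(n_markers),
        "n_phenotypes": int(n_phenotypes),
        "n_genotype_observations": int(n_subjects) * int(n_markers),
        "n_regressions": int(n_markers) * int(n_phenotypes),
    }
    out.update(counts)
    return out


def _screen_matrices(
    study: GenotypeStudy, policy: str
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Genotype matrix for the vectorized screen plus per-marker exclusion masks.

    The screen needs complete data; under ``drop_per_marker`` missing cells
    are mean-imputed for screening only, while the exact pass uses the masks.
    """
    if not (study.dosage == MISSING).any():
        return study.dosage, {}
    if policy == "error":
        # raises with the missing-cell count
        to_design_matrix(study, "error")
    X, _ = to_design_matrix(study, "mean_impute")
    if policy == "mean_impute":
        return X, {}
    _, masks = to_design_matrix(study, "drop_per_marker")
    return X, masks


def _result_row(res: AssociationResult, study: GenotypeStudy) -> dict:
    mk = study.markers[res.marker_index]
    ok = res.status in (STATUS_OK, "max_iter") and np.isfinite(res.se)
    with np.errstate(over="ignore"):  # huge betas from quasi-separated fits -> inf -> "NA"
        return {
            "CHR": mk.chrom,
            "SNP": mk.id,
            "BP": mk.bp,
            "A1": mk.a1,
            "TEST": "ADD",
            "NMISS": res.n_used,
            "OR": np.exp(res.beta_g) if ok else np.nan,
            "SE": res.se if ok else np.nan,
            "L95": np.exp(res.beta_g - CI_Z * res.se) if ok else np.nan,
            "U95": np.exp(res.beta_g + CI_Z * res.se) if ok else np.nan,
            "STAT": res.beta_g / res.se if ok else np.nan,
            "P": res.p,
            "PHENO": res.phenotype_index + 1,
        }


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def _finalize_table(rows: list[dict], flagged: Optional[list[bool]]) -> pd.DataFrame:
    cols = ASSOC_COLUMNS + ["PHENO"]
    df = pd.DataFrame(rows, columns=cols)
    if flagged is not None:
        df["FLAG"] = ["ABOVE_CUTOFF" if f else "PASS" for f in flagged]
    if len(df):
        key = df["CHR"].map(_chrom_key)
        df = (
            df.assign(_ck=key)
            .sort_values(["PHENO", "_ck", "BP", "SNP"], kind="mergesort")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
    return df


def run_association(
    study: GenotypeStudy,
    phenotypes: np.ndarray,
    covariates: Optional[np.ndarray],
    cfg: ScreenConfig,
) -> AssociationRun:
    """Run the association workflow in ``exact``, ``fast`` or ``two_pass`` mode.

    ``phenotypes`` is N x P with entries in {0, 1} (NaN marks a subject
    missing that phenotype and excluded from its fits); ``covariates`` is
    N x C *without* the intercept column (None for covariate-free models).

    Returns the PLINK-style report table (rows sorted by phenotype, then
    chromosome and position), the per-marker screen table for screening modes,
    and a bookkeeping summary.
    """
    phenotypes = np.atleast_2d(np.asarray(phenotypes, dtype=np.float64))
    if phenotypes.shape[0] == 1 and study.n_subjects != 1:
        phenotypes = phenotypes.T
    n, m = study.n_subjects, study.n_markers
    if phenotypes.shape[0] != n:
        raise ValueError("phenotype rows do not match the study")
    n_pheno = phenotypes.shape[1]
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=np.float64)
    if covariates.shape[0] != n:
        raise ValueError("covariate rows do not match the study")

    G_screen, masks = _screen_matrices(study, cfg.missing_policy)
    chunks = chunk_markers(m, cfg.n_chunks)

    all_results: list[AssociationResult] = []
    rows: list[dict] = []
    flagged: list[bool] = []
    screen_frames: list[pd.DataFrame] = []
    n_screened = n_retained = 0

    for ph in range(n_pheno):
        col = phenotypes[:, ph]
        obs = np.isfinite(col)
        yp = col[obs]
        bad = yp[~np.isin(yp, (0.0, 1.0))]
        if bad.size:
            raise ValueError(
                f"phenotype {ph}: non-binary values {np.unique(bad)[:5].tolist()}"
            )
        Xc = np.column_stack([np.ones(obs.sum()), covariates[obs]])
        Gp = G_screen[obs]
        warm = fit_covariate_only(yp, Xc, tol=cfg.tol, max_iter=cfg.max_iter, ridge=cfg.ridge)
        if warm.status == STATUS_SEPARATION:
            raise ValueError(f"phenotype {ph} is constant (all-{int(yp[0])}); cannot fit")
        # exclusion masks re-indexed to the phenotype's observed subjects
        if masks:
            pos = np.cumsum(obs) - 1
            masks_p = {
                j: pos[rows_]
                for j, rows_ in ((j, r[obs[r]]) for j, r in masks.items())
                if rows_.size
            }
        else:
            masks_p = {}

        if cfg.mode == "exact":
            res = []
            for a, b in chunks:
                res.extend(
                    exact_scan(
                        Gp, yp, Xc, warm=warm, marker_indices=range(a, b),
                        tol=cfg.tol, max_iter=cfg.max_iter, ridge=cfg.ridge,
                        masks=masks_p, phenotype_index=ph,
                    )
                )
            all_results.extend(res)
            rows.extend(_result_row(r, study) for r in res)
            continue

        z2s = one_step_screen(Gp, yp, Xc, warm)
        p_screen = np.asarray(chisq1_p(z2s))

        if cfg.mode == "fast":
            res = []
            for a, b in chunks:
                res.extend(
                    fast_scan(
                        Gp, yp, Xc, warm, marker_indices=range(a, b),
                        fast_iters=cfg.fast_iters, tol=cfg.tol, ridge=cfg.ridge,
                        phenotype_index=ph,
                    )
                )
            all_results.extend(res)
            rows.extend(_result_row(r, study) for r in res)
            screen_frames.append(_screen_frame(study, ph, z2s, p_screen, np.ones(m, bool)))
            continue

        # two-pass: fast refits for screen survivors, exact refits for retained
        gate = cfg.screen_gate
        survivors = np.nonzero(p_screen <= gate)[0]
        n_screened += survivors.size
        fast_results: list[AssociationResult] = []
        for a, b in chunks:
            sub = survivors[(survivors >= a) & (survivors < b)]
            fast_results.extend(
                fast_scan(
                    Gp, yp, Xc, warm, marker_indices=sub,
                    fast_iters=cfg.fast_iters, tol=cfg.tol, ridge=cfg.ridge,
                    phenotype_index=ph,
                )
            )
        retained = [r.marker_index for r in fast_results if r.p <= gate]
        n_retained += len(retained)
        retained_mask = np.zeros(m, dtype=bool)
        retained_mask[retained] = True
        screen_frames.append(_screen_frame(study, ph, z2s, p_screen, retained_mask))

        final = []
        for a, b in chunks:
            sub = [j for j in retained if a <= j < b]
            final.extend(
                exact_scan(
                    Gp, yp, Xc, warm=warm, marker_indices=sub,
                    tol=cfg.tol, max_iter=cfg.max_iter, ridge=cfg.ridge,
                    masks=masks_p, phenotype_index=ph,
                )
            )
        all_results.extend(final)
        for r in final:
            rows.append(_result_row(r, study))
            flagged.append(r.p > cfg.screen_p_cutoff)

    table = _finalize_table(rows, flagged if cfg.mode == "two_pass" else None)
    screen = pd.concat(screen_frames, ignore_index=True) if screen_frames else None
    summary = pipeline_summary(
        n, m, n_pheno,
        mode=cfg.mode,
        n_markers_screened=int(n_screened),
        n_markers_retained=int(n_retained),
        n_rows_reported=len(table),
    )
    return AssociationRun(table=table, screen=screen, summary=summary, results=all_results)


def _screen_frame(study, ph, z2s, p_screen, retained_mask) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": [mk.id for mk in study.markers],
            "PHENO": ph + 1,
            "Z2_FAST": z2s,
            "P_FAST": p_screen,
            "RETAINED": retained_mask.astype(int),
        }
    )


def two_pass(
    study: GenotypeStudy,
    phenotypes: np.ndarray,
    covariates: Optional[np.ndarray],
    cfg: Optional[ScreenConfig] = None,
) -> AssociationRun:
    """Screen every marker, then exactly refit and report the survivors."""
    cfg = cfg or ScreenConfig()
    if cfg.mode != "two_pass":
        cfg = ScreenConfig(**{**cfg.__dict__, "mode": "two_pass"})
    return run_association(study, phenotypes, covariates, cfg)


def _fmt(v, width: int) -> str:
    if isinstance(v, float):
        if not np.isfinite(v):
            s = "NA"
        elif v != 0 and (abs(v) < 1e-3 or abs(v) >= 1e5):
            s = f"{v:.4g}"
        else:
            s = f"{v:.4f}"
    else:
        s = str(v)
    return s.rjust(width)


def write_assoc_logistic(table: pd.DataFrame, path) -> None:
    """Write the report in the PLINK 1.07 ``.assoc.logistic`` dialect.

    The PHENO column is emitted only for multi-phenotype runs; the FLAG
    column (two-pass near-cutoff audit trail) is emitted when present.
    """
    cols = list(ASSOC_COLUMNS)
    if "PHENO" in table.columns and table["PHENO"].nunique() > 1:
        cols = ["PHENO"] + cols
    if "FLAG" in table.columns:
        cols = cols + ["FLAG"]
    widths = {c: max(len(c), 12) if c in ("OR", "SE", "L95", "U95", "STAT", "P") else max(len(c), 6) for c in cols}
    with open(path, "w") as fh:
        fh.write(" ".join(c.rjust(widths[c]) for c in cols) + "\n")
        for _, row in table.iterrows():
            fh.write(" ".join(_fmt(row[c], widths[c]) for c in cols) + "\n")


def write_screen_file(screen: pd.DataFrame, path) -> None:
    """Write the per-marker screen table (TSV: id, fast z2, fast p, retained)."""
    screen.to_csv(path, sep="\t", index=False, float_format="%.6g")
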