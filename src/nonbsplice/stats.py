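"""Association statistics for intronic non-B DNA motifs and exon skipping.

The statistical layer mirrors a four-pronged analysis:

1. stratified skipping proportions compared against the background skipping
   probability (per class / region / strand / occurrence count, and per
   maximum G-run length for G4);
2. partial Pearson correlation between occurrence count and the binary
   skipping indicator adjusting for intron length (residual-on-residual
   correlation; t approximation with n - 3 degrees of freedom);
3. a one-sided two-sample proportion test (pooled variance, no continuity
   correction) comparing the fraction of skipped vs. constitutive exons
   whose exon-proximal window carries at least one occurrence;
4. a 12-predictor multiple logistic regression of the skipping indicator on
   upstream/downstream intron length plus the per-region occurrence counts
   of the five structure classes (G4 strands summed), with Wald z tests.

P-values are reported raw; a Benjamini-Hochberg column can be added to the
emitted tables but never gates any result.  Significance stars follow the
convention * P < 0.01, ** P < 0.001, *** P < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedProportion",
    "PartialCorrelationResult",
    "ProportionTestResult",
    "LogisticFit",
    "SeparationError",
    "DegenerateStatisticError",
    "partial_pearson",
    "two_sample_proportion_test",
    "group_proportions",
    "build_design_matrix",
    "fit_logistic",
    "proximal_comparison",
    "g_run_association",
    "significance_stars",
    "add_bh_column",
    "DESIGN_COLUMNS",
    "STRUCTURE_COLUMNS",
]

#: structure count columns of the profile frame, split by G4 strand
STRUCTURE_COLUMNS = (
    "g4_template",
    "g4_nontemplate",
    "cruciform",
    "slipped",
    "triplex",
    "zdna",
)

#: fixed 12-column order of the logistic design matrix
DESIGN_COLUMNS = (
    "upstream_length",
    "downstream_length",
    "upstream_cruciform",
    "upstream_g4",
    "upstream_slipped",
    "upstream_triplex",
    "upstream_zdna",
    "downstream_cruciform",
    "downstream_g4",
    "downstream_slipped",
    "downstream_triplex",
    "downstream_zdna",
)


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: no finite ML estimate exists."""


class DegenerateStatisticError(ValueError):
    """A statistic is undefined (zero variance or degenerate proportions)."""


@dataclass(frozen=True)
class GroupedProportion:
    stratum: tuple
    n_exons: int
    n_skipped: int
    proportion: float
    background: float


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    t_stat: float
    df: int
    p_value: float
    n: int


@dataclass(frozen=True)
class ProportionTestResult:
    p1: float
    p2: float
    z_stat: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    converged: bool
    n_iterations: int
    log_likelihood: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.standard_errors,
                "wald_z": self.wald_z,
                "p_value": self.p_values,
            }
        )


def significance_stars(p: float) -> str:
    """Star codes: * P < 0.01, ** P < 0.001, *** P < 0.0001."""
    if not np.isfinite(p):
        return ""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return ""


def add_bh_column(table: pd.DataFrame, p_col: str = "p_value") -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted column ``q_value`` (informative
    only; nothing is filtered on it)."""
    from statsmodels.stats.multitest import multipletests

    table = table.copy()
    mask = table[p_col].notna()
    q = np.full(len(table), np.nan)
    if mask.any():
        q[mask.to_numpy()] = multipletests(
            table.loc[mask, p_col].to_numpy(), method="fdr_bh"
        )[1]
    table["q_value"] = q
    return table


# ---------------------------------------------------------------------------
# partial correlation

def partial_pearson(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    alternative: str = "two-sided",
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y adjusting for z.

    Computed as the plain Pearson correlation between the least-squares
    residuals of x on z and of y on z (each regression includes an
    intercept).  The test statistic is ``t = r * sqrt((n - 3) / (1 - r^2))``
    referred to a t distribution with ``n - 3`` degrees of freedom.
    ``alternative`` is ``"two-sided"``, ``"greater"`` or ``"less"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if len(y) != n or len(z) != n:
        raise ValueError("x, y and z must have equal length")
    if n < 4:
        raise ValueError("partial correlation requires n >= 4")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    scale = max(float(x @ x), 1.0) * 1e-24
    if sx <= scale or sy <= max(float(y @ y), 1.0) * 1e-24:
        raise DegenerateStatisticError(
            "partial correlation undefined: zero residual variance"
        )
    r = float(rx @ ry / np.sqrt(sx * sy))
    r = min(1.0, max(-1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PartialCorrelationResult(r, float(t), df, float(min(p, 1.0)), n)


# ---------------------------------------------------------------------------
# proportion test

def two_sample_proportion_test(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "greater"
) -> ProportionTestResult:
    """One-sided two-sample proportion test with pooled variance and no
    continuity correction; default alternative: p1 > p2."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateStatisticError(
            "pooled proportion is degenerate (0 or 1); z undefined"
        )
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    if alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ProportionTestResult(p1, p2, float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# stratified proportions

def _require_profile_columns(profiles: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile frame lacks columns: {missing}")


def group_proportions(
    profiles: pd.DataFrame,
    background: Optional[float] = None,
    stratifier: str = "count",
) -> pd.DataFrame:
    """Skipping proportion per stratum.

    With ``stratifier="count"`` strata are (structure, region, count) for
    every observed count >= 1, where ``structure`` iterates over the
    strand-split classes; with ``stratifier="g_run"`` strata are (strand,
    region, maximum G-run length) over G4-bearing introns.  Rows carry the
    shared background proportion; an all-skipped stratum has proportion 1.0
    and empty strata are simply absent (n_exons would be 0).
    """
    _require_profile_columns(profiles, ["entry_id", "label", "region"])
    if background is None:
        per_exon = profiles.drop_duplicates("entry_id")
        background = float((per_exon["label"] == "SKIPPED").mean())
    rows = []
    if stratifier == "count":
        for structure in STRUCTURE_COLUMNS:
            col = f"n_{structure}"
            _require_profile_columns(profiles, [col])
            sub = profiles[profiles[col] > 0]
            grouped = sub.groupby(["region", col], sort=True)
            for (region, count), grp in grouped:
                n = len(grp)
                k = int((grp["label"] == "SKIPPED").sum())
                rows.append(
                    {
                        "structure": structure,
                        "region": region,
                        "count": int(count),
                        "n_exons": n,
                        "n_skipped": k,
                        "proportion": k / n,
                        "background": background,
                    }
                )
        cols = ["structure", "region", "count", "n_exons", "n_skipped",
                "proportion", "background"]
    elif stratifier == "g_run":
        _require_profile_columns(
            profiles, ["max_g_run_template", "max_g_run_nontemplate"]
        )
        for strand in ("template", "nontemplate"):
            col = f"max_g_run_{strand}"
            sub = profiles[profiles[col] > 0]
            for (region, length), grp in sub.groupby(["region", col], sort=True):
                n = len(grp)
                k = int((grp["label"] == "SKIPPED").sum())
                rows.append(
                    {
                        "strand": strand,
                        "region": region,
                        "g_run_length": int(length),
                        "n_exons": n,
                        "n_skipped": k,
                        "proportion": k / n,
                        "background": background,
                    }
                )
        cols = ["strand", "region", "g_run_length", "n_exons", "n_skipped",
                "proportion", "background"]
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# logistic regression

def build_design_matrix(
    profiles: pd.DataFrame, merge_g4_strands: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot the long profile frame into the 12-predictor design matrix.

    Column order is fixed (:data:`DESIGN_COLUMNS`): upstream length,
    downstream length, then the five per-region occurrence counts
    (cruciform, G4, slipped, triplex, Z-DNA) for upstream then downstream.
    The G4 count sums template and non-template hits unless
    ``merge_g4_strands`` is false, in which case the matrix has 14 columns
    with the two G4 strands kept separate.  ``y`` is 1 for SKIPPED.
    Raises when an exon lacks one of its two region profiles.
    """
    _require_profile_columns(
        profiles,
        ["entry_id", "label", "region", "intron_length"]
        + [f"n_{s}" for s in STRUCTURE_COLUMNS],
    )
    counts = profiles.copy()
    counts["n_g4"] = counts["n_g4_template"] + counts["n_g4_nontemplate"]
    wide = counts.pivot(index="entry_id", columns="region")
    if merge_g4_strands:
        per_region = ["cruciform", "g4", "slipped", "triplex", "zdna"]
    else:
        per_region = [
            "cruciform", "g4_template", "g4_nontemplate", "slipped",
            "triplex", "zdna",
        ]
    cols = {}
    for region in ("upstream", "downstream"):
        try:
            cols[f"{region}_length"] = wide[("intron_length", region)]
            for s in per_region:
                cols[f"{region}_{s}"] = wide[(f"n_{s}", region)]
        except KeyError:
            raise ValueError(f"profiles lack the {region} region") from None
    X = pd.DataFrame(cols)
    if X.isna().any().any():
        bad = X.index[X.isna().any(axis=1)][0]
        raise ValueError(f"exon {bad!r} is missing a region profile")
    order = (
        list(DESIGN_COLUMNS)
        if merge_g4_strands
        else ["upstream_length", "downstream_length"]
        + [f"upstream_{s}" for s in per_region]
        + [f"downstream_{s}" for s in per_region]
    )
    X = X[order].astype(float)
    labels = profiles.drop_duplicates("entry_id").set_index("entry_id")["label"]
    y = (labels.reindex(X.index) == "SKIPPED").astype(int)
    y.name = "skipped"
    return X, y


def fit_logistic(X, y, maxiter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald z statistics.

    Fitted by Newton-Raphson (iteratively reweighted least squares) with an
    intercept prepended; coefficients are unstandardized (per-unit change
    on the logit scale).  Non-convergence or perfect separation raises
    :class:`SeparationError`.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    if X.shape[1] == 0:  # intercept-only model
        design = pd.DataFrame({"intercept": np.ones(len(X))}, index=X.index)
    else:
        design = sm.add_constant(X, prepend=True, has_constant="add")
        design = design.rename(columns={"const": "intercept"})
    model = sm.Logit(y, design)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    bse = np.asarray(res.bse, dtype=float)
    if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(bse)):
        raise SeparationError(
            "logistic fit did not converge (possible quasi-separation)"
        )
    coef = pd.Series(res.params, index=design.columns)
    se = pd.Series(bse, index=design.columns)
    z = coef / se
    p = pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=design.columns)
    return LogisticFit(
        coefficients=coef,
        standard_errors=se,
        wald_z=z,
        p_values=p,
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", -1)),
        log_likelihood=float(res.llf),
    )


# ---------------------------------------------------------------------------
# proximal comparison (skipped vs constitutive within 500 bp)

def proximal_comparison(
    profiles: pd.DataFrame, alternative: str = "greater"
) -> pd.DataFrame:
    """Per (structure, region): compare the fraction of skipped vs.
    constitutive exons with at least one occurrence in the exon-proximal
    window (presence/absence, not raw counts); one-sided alternative
    skipped > constitutive by default."""
    _require_profile_columns(
        profiles, ["label", "region"] + [f"prox_{s}" for s in STRUCTURE_COLUMNS]
    )
    is_skip = profiles["label"] == "SKIPPED"
    if is_skip.all() or (~is_skip).all():
        raise ValueError("need both skipped and constitutive exons")
    rows = []
    for region in ("upstream", "downstream"):
        reg = profiles[profiles["region"] == region]
        skip = reg[reg["label"] == "SKIPPED"]
        cons = reg[reg["label"] == "CONSTITUTIVE"]
        for structure in STRUCTURE_COLUMNS:
            k1 = int((skip[f"prox_{structure}"] > 0).sum())
            k2 = int((cons[f"prox_{structure}"] > 0).sum())
            try:
                res = two_sample_proportion_test(
                    k1, len(skip), k2, len(cons), alternative
                )
                z, p = res.z_stat, res.p_value
            except DegenerateStatisticError:
                z, p = np.nan, np.nan
            rows.append(
                {
                    "region": region,
                    "structure": structure,
                    "skipped_pct": 100.0 * k1 / len(skip),
                    "constitutive_pct": 100.0 * k2 / len(cons),
                    "n_skipped": len(skip),
                    "n_constitutive": len(cons),
                    "z_stat": z,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# G-run length association

def g_run_association(
    profiles: pd.DataFrame, background: Optional[float] = None
) -> tuple[pd.DataFrame, PartialCorrelationResult]:
    """Skipping proportion per (strand, region, maximum G-run length) plus
    the partial correlation of G-run length with skipping adjusting for
    intron length, pooled over all G4-bearing (exon, region, strand)
    observations."""
    table = group_proportions(profiles, background, stratifier="g_run")
    xs, ys, zs = [], [], []
    for strand in ("template", "nontemplate"):
        col = f"max_g_run_{strand}"
        sub = profiles[profiles[col] > 0]
        xs.append(sub[col].to_numpy(dtype=float))
        ys.append((sub["label"] == "SKIPPED").to_numpy(dtype=float))
        zs.append(sub["intron_length"].to_numpy(dtype=float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    z = np.concatenate(zs)
    if len(x) == 0:
        raise ValueError("no G4-bearing introns")
    try:
        corr = partial_pearson(x, y, z)
    except DegenerateStatisticError as exc:
        raise DegenerateStatisticError(
            f"G-run association: {exc} (constant G-run length or labels)"
        ) from exc
    return table, corr
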