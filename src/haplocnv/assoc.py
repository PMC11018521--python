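"""Association testing: phenotype preparation, OLS association, pLOF burden
collapsing, LD/conditional filtering, and the WGS validation-rate statistic.

Quantitative phenotypes are rank-based inverse-normal transformed within
strata and residualized on covariates before testing.  Association uses
ordinary least squares with covariates (a linear mixed model would add
relatedness modeling; that is a stated limitation of this package, not a
silent simplification).  Gene-level burden masks collapse pLOF carriers
across variant classes (CNV, SNV, indel).  The LD filter conditions a target
association on nearby imputed variants to drop signals explainable by
linkage.  The validation-rate statistic summarizes orthogonal WGS read-depth
support for a CNV call set: false positives should be equally likely to show
WGS depth in either direction, so correct-minus-opposite fractions estimate
the true-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import rankdata

from .rarecnv import CNVCall

__all__ = [
    "PreparedPhenotype",
    "AssociationResult",
    "BurdenMask",
    "LDFilterResult",
    "inverse_normal_transform",
    "prep_phenotype",
    "test_association",
    "burden_collapse",
    "ld_filter",
    "validation_rate",
]

GENOME_WIDE_P = 5e-8


@dataclass
class PreparedPhenotype:
    values: pd.Series
    strata: list[str]
    covariates: list[str]


@dataclass
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    p_value: float
    n: int
    genome_wide: bool = False

    def __post_init__(self) -> None:
        self.genome_wide = bool(self.p_value < GENOME_WIDE_P)


@dataclass
class BurdenMask:
    gene: str
    indicator: pd.Series
    classes: list[str]
    carrier_count: int


@dataclass
class LDFilterResult:
    variant_id: str
    passed: bool
    marginal_beta: float
    marginal_p: float
    conditional_beta: float
    conditional_p: float
    selected_variants: list[str]
    max_r2: float


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with offset (r - 0.5)/n; midranks for ties."""
    r = rankdata(x, method="average")
    return ndtri((r - 0.5) / len(x))


_int_transform = inverse_normal_transform


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def prep_phenotype(
    raw: pd.Series,
    strata: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    min_stratum: int = 30,
) -> PreparedPhenotype:
    """Within-stratum inverse normal transform, covariate residualization and
    re-standardization of a quantitative phenotype."""
    if raw.nunique() <= 1:
        raise ValueError("constant phenotype")
    if strata is None:
        strata = pd.Series("all", index=raw.index)
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    labels = []
    for label, idx in strata.groupby(strata).groups.items():
        if len(idx) < min_stratum:
            raise ValueError(f"stratum {label!r} has fewer than {min_stratum} samples")
        y = _int_transform(raw.loc[idx].to_numpy(dtype=float))
        cov = covariates.loc[idx].to_numpy(dtype=float) if covariates is not None else None
        y = _residualize(y, cov)
        sd = y.std(ddof=1)
        if sd > 0:
            y = (y - y.mean()) / sd
        out.loc[idx] = y
        labels.append(str(label))
    cov_names = list(covariates.columns) if covariates is not None else []
    return PreparedPhenotype(values=out, strata=labels, covariates=cov_names)


def test_association(
    genotype: pd.Series | np.ndarray,
    phenotype: PreparedPhenotype | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant_id: str = "variant",
    min_overlap: int = 100,
) -> AssociationResult:
    """OLS of the prepared phenotype on a genotype/dosage plus covariates."""
    y = phenotype.values if isinstance(phenotype, PreparedPhenotype) else phenotype
    if isinstance(genotype, pd.Series) and isinstance(y, pd.Series):
        common = genotype.index.intersection(y.index)
        x = genotype.loc[common].to_numpy(dtype=float)
        yv = y.loc[common].to_numpy(dtype=float)
        cov = covariates.loc[common].to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else covariates
    else:
        x = np.asarray(genotype, dtype=float)
        yv = np.asarray(y, dtype=float)
        cov = np.asarray(covariates, dtype=float) if covariates is not None else None
    if len(x) < min_overlap:
        raise ValueError("fewer than the minimum overlapping samples")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    cols = [np.ones(len(x)), x]
    names = ["const", variant_id]
    if cov is not None and np.size(cov):
        cov = np.atleast_2d(cov)
        if cov.shape[0] != len(x):
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(
                covariates.columns[j] if isinstance(covariates, pd.DataFrame) else f"cov{j}"
            )
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending column for the error message
        for j in range(2, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"covariate {names[j]!r} is collinear with the predictor")
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(yv, X).fit()
    return AssociationResult(
        variant_id=variant_id,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=len(x),
    )


test_association.__test__ = False  # an estimator, not a pytest case


def burden_collapse(
    gene: str,
    carriers_by_class: dict[str, set[str]],
    samples: list[str],
) -> dict[str, BurdenMask | None]:
    """Gene-level pLOF burden masks.

    Returns two masks: ``all`` (union of CNV + SNV + indel pLOF carriers) and
    ``snv_indel`` (SNV/indel classes only), so the gain from adding CNVs to
    the burden can be measured.  A mask with no carriers is returned as None.
    """
    def _mask(classes: list[str]) -> BurdenMask | None:
        union: set[str] = set()
        present = []
        for cls in classes:
            members = carriers_by_class.get(cls, set())
            if members:
                present.append(cls)
            union |= set(members)
        union &= set(samples)
        if not union:
            return None
        ind = pd.Series(0, index=samples, dtype=int)
        ind.loc[sorted(union)] = 1
        return BurdenMask(gene=gene, indicator=ind, classes=present, carrier_count=len(union))

    all_classes = sorted(carriers_by_class)
    snv_indel = [c for c in all_classes if "CNV" not in c.upper()]
    return {"all": _mask(all_classes), "snv_indel": _mask(snv_indel)}


def ld_filter(
    target: pd.Series,
    local_variants: pd.DataFrame,
    phenotype: PreparedPhenotype | pd.Series,
    covariates: pd.DataFrame | None = None,
    p_cond: float = 0.01,
    k_max: int = 10,
    r2_min: float = 0.01,
    r2_collinear: float = 0.999,
    variant_id: str = "target",
) -> LDFilterResult:
    """Conditional test of a target association against nearby variants.

    Up to ``k_max`` local variants (those with r^2 >= ``r2_min`` to the
    target) are selected in order of marginal association p-value; the target
    is then re-tested conditional on the selection.  The association passes
    iff the conditional p stays below ``p_cond`` and the conditional effect
    retains at least half the marginal effect.  A local variant essentially
    identical to the target (r^2 >= ``r2_collinear``) fails immediately.
    """
    y = phenotype.values if isinstance(phenotype, PreparedPhenotype) else phenotype
    yv = np.asarray(y, dtype=float)
    x = np.asarray(target, dtype=float)
    marginal = test_association(x, yv, covariates, variant_id=variant_id)

    r2s: dict[str, float] = {}
    for name in local_variants.columns:
        v = local_variants[name].to_numpy(dtype=float)
        if np.std(v) == 0:
            r2s[name] = 0.0
        else:
            r2s[name] = float(np.corrcoef(x, v)[0, 1] ** 2)
    max_r2 = max(r2s.values(), default=0.0)
    if max_r2 >= r2_collinear:
        return LDFilterResult(
            variant_id, False, marginal.beta, marginal.p_value,
            0.0, 1.0, [max(r2s, key=r2s.get)], max_r2,
        )
    cands = [n for n in local_variants.columns if r2s[n] >= r2_min]
    if not cands:
        return LDFilterResult(
            variant_id, True, marginal.beta, marginal.p_value,
            marginal.beta, marginal.p_value, [], max_r2,
        )
    marg_p = {
        n: test_association(local_variants[n].to_numpy(dtype=float), yv, covariates, variant_id=n).p_value
        for n in cands
    }
    selected = sorted(cands, key=lambda n: (marg_p[n], n))[:k_max]

    cov_cols = [local_variants[n].to_numpy(dtype=float) for n in selected]
    if covariates is not None:
        cov_cols = [covariates.to_numpy(dtype=float)] + cov_cols
    cond_cov = np.column_stack(cov_cols)
    cond = test_association(x, yv, cond_cov, variant_id=variant_id)
    passed = cond.p_value < p_cond and abs(cond.beta) >= 0.5 * abs(marginal.beta)
    return LDFilterResult(
        variant_id, bool(passed), marginal.beta, marginal.p_value,
        cond.beta, cond.p_value, selected, max_r2,
    )


def validation_rate(
    calls: list[CNVCall],
    wgs_estimates: list[float],
    delta: float = 0.1,
) -> tuple[float, pd.DataFrame]:
    """Direction-difference validation rate against orthogonal WGS depth.

    Each call's mean normalized WGS copy estimate over its interval is
    compared with the diploid level 2: a verdict is correct if the shift
    matches the call type (deletion below, duplication above), opposite if it
    mismatches, and ambiguous if |estimate - 2| < ``delta``.  V =
    frac(correct) - frac(opposite) over calls with an estimate; calls with a
    missing estimate are excluded from the denominator and reported
    separately.
    """
    if len(calls) != len(wgs_estimates):
        raise ValueError("need one WGS estimate per call")
    verdicts = []
    for call, est in zip(calls, wgs_estimates):
        if est is None or (isinstance(est, float) and np.isnan(est)):
            verdicts.append("missing")
        elif abs(est - 2.0) < delta:
            verdicts.append("ambiguous")
        elif (est < 2.0 and call.type == "DEL") or (est > 2.0 and call.type == "DUP"):
            verdicts.append("correct")
        else:
            verdicts.append("opposite")
    table = pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "type": [c.type for c in calls],
            "wgs_estimate": wgs_estimates,
            "verdict": verdicts,
        }
    )
    assessed = table[table["verdict"] != "missing"]
    n = len(assessed)
    if n == 0:
        return float("nan"), table
    v = (
        (assessed["verdict"] == "correct").sum() - (assessed["verdict"] == "opposite").sum()
    ) / n
    return float(v), table
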