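"""Inter-rater agreement, label distributions, and multinomial-regression tests.

Agreement between two raters is the raw percentage of patients to whom both
assigned the identical label (no chance correction).  The association
between a video descriptor and a rater's labels is tested with a
multinomial logistic regression: the likelihood-ratio statistic
LR = 2(ll_full - ll_null) against an intercepts-only baseline, referred to
a chi-square with (K-1) x p degrees of freedom for K observed classes and
p predictors.  With n ~ 25 patients and up to 12 subtype classes, fits can
be infeasible (more parameters than observations) or separable; infeasible
cells are reported as skipped with a reason, separable ones fall back to a
bounded-iteration ridge-regularized fit and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .facegrid import REGION_NAMES, CellIntensitySeries, FacePartition
from .features import motion_feature
from .vocab import DOMAINS

ANNOTATION_COLUMNS = ("patient_id", "rater_id", "domain", "label")


@dataclass
class AnnotationTable:
    """Tidy table of (patient, rater, domain, label) affect annotations."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns {sorted(missing)}")
        self.df = self.df.loc[:, list(ANNOTATION_COLUMNS)].reset_index(drop=True)
        dup = self.df.duplicated(subset=["patient_id", "rater_id", "domain"])
        if dup.any():
            raise ValueError(
                "duplicate annotations for "
                f"{self.df.loc[dup, ['patient_id', 'rater_id', 'domain']].values.tolist()}"
            )
        for domain, grp in self.df.groupby("domain"):
            if domain not in DOMAINS:
                raise ValueError(f"unknown affect domain {domain!r}")
            bad = sorted(set(grp["label"]) - set(DOMAINS[domain]))
            if bad:
                raise ValueError(f"labels outside the {domain} vocabulary: {bad}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "AnnotationTable":
        return cls(pd.DataFrame.from_records(records, columns=ANNOTATION_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.df.sort_values(["patient_id", "rater_id", "domain"]).to_csv(path, index=False)

    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    def raters(self) -> list[str]:
        return sorted(self.df["rater_id"].unique())

    def labels_for(self, rater_id: str, domain: str, patients: list[str] | None = None) -> list[str]:
        sub = self.df[(self.df["rater_id"] == rater_id) & (self.df["domain"] == domain)]
        mapping = dict(zip(sub["patient_id"], sub["label"]))
        patients = patients if patients is not None else sorted(mapping)
        missing = [p for p in patients if p not in mapping]
        if missing:
            raise ValueError(f"rater {rater_id!r} lacks {domain} labels for {missing}")
        return [mapping[p] for p in patients]


@dataclass
class AgreementMatrix:
    """Symmetric rater-by-rater percent-identical-annotation matrix."""

    values: np.ndarray  # (n_raters, n_raters), percent
    raters: tuple[str, ...]
    domain: str
    n_patients: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.raters)
        if self.values.shape != (r, r):
            raise ValueError("matrix shape must match the rater list")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("agreement matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0, atol=1e-9):
            raise ValueError("self-agreement must be 100%")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("agreement entries must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.raters), columns=list(self.raters))


def pairwise_agreement(table: AnnotationTable, domain: str) -> AgreementMatrix:
    """Percent of patients with identical labels, for every rater pair.

    Entry (i, j) is 100 x (#patients labeled identically by raters i and j)
    / n_patients.  Every rater must label every patient in the domain.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown affect domain {domain!r}")
    sub = table.df[table.df["domain"] == domain]
    if sub.empty:
        raise ValueError(f"no annotations for domain {domain!r}")
    pivot = sub.pivot(index="patient_id", columns="rater_id", values="label")
    if pivot.isna().any().any():
        missing = [
            (p, r) for p, row in pivot.iterrows() for r in pivot.columns if pd.isna(row[r])
        ]
        raise ValueError(f"missing annotations for (patient, rater) pairs: {missing}")
    raters = tuple(sorted(pivot.columns))
    arr = pivot.loc[:, list(raters)].to_numpy()
    n = arr.shape[0]
    values = np.array(
        [[100.0 * np.count_nonzero(arr[:, i] == arr[:, j]) / n for j in range(len(raters))]
         for i in range(len(raters))]
    )
    return AgreementMatrix(values, raters, domain, n)


def agreement_summary(matrix: AgreementMatrix) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of the unique off-diagonal agreement entries."""
    r = len(matrix.raters)
    if r < 2:
        raise ValueError("agreement summary needs at least 2 raters")
    iu = np.triu_indices(r, k=1)
    vals = matrix.values[iu]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return mean, sd


@dataclass
class LabelDistribution:
    """Per-rater label frequencies for one domain, with the modal label."""

    rater_id: str
    domain: str
    counts: dict[str, int]
    percentages: dict[str, float]
    most_common: str
    most_common_pct: float
    n: int


def label_distribution(table: AnnotationTable, rater_id: str, domain: str) -> LabelDistribution:
    """Label percentages for one rater and domain (ties: fixed label order)."""
    labels = table.df[
        (table.df["rater_id"] == rater_id) & (table.df["domain"] == domain)
    ]["label"].tolist()
    if not labels:
        raise ValueError(f"rater {rater_id!r} has no {domain} annotations")
    n = len(labels)
    counts = {lab: labels.count(lab) for lab in DOMAINS[domain]}
    pct = {lab: 100.0 * c / n for lab, c in counts.items()}
    most_common = max(DOMAINS[domain], key=lambda lab: counts[lab])  # first max in fixed order
    return LabelDistribution(rater_id, domain, counts, pct, most_common, pct[most_common], n)


# ---------------------------------------------------------------------------
# Multinomial logistic regression, likelihood-ratio test


@dataclass
class LrtResult:
    statistic: float | None
    df: int | None
    pvalue: float | None
    n: int
    n_classes: int
    n_predictors: int
    converged: bool = True
    flagged: bool = False  # regularized fallback used (e.g. perfect separation)
    dropped_predictors: int = 0
    skipped_reason: str | None = None


def _null_loglik(codes: np.ndarray) -> float:
    n = codes.size
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    return float(np.sum(counts * np.log(counts / n)))


def multinomial_lrt(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    class_order: tuple[str, ...] | None = None,
    maxiter: int = 200,
) -> LrtResult:
    """LR test of a multinomial logit with predictors vs. intercepts only.

    Zero-variance predictors are dropped with a warning.  Returns a skipped
    result (no statistic) when fewer than 2 classes are observed or when
    the sample cannot support the parameter count; falls back to a flagged
    ridge-regularized bounded-iteration fit when the unpenalized fit fails
    (perfect separation).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = [str(l) for l in y]
    n = len(y)
    if len(X) != n:
        raise ValueError("one outcome label per predictor row required")
    observed = sorted(set(y), key=(class_order or sorted(set(y))).index)
    K = len(observed)
    if K < 2:
        return LrtResult(None, None, None, n, K, X.shape[1],
                         skipped_reason="single observed class")
    keep = X.std(axis=0) > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} zero-variance predictor(s)", stacklevel=2)
    X = X[:, keep]
    p = X.shape[1]
    codes = np.array([observed.index(l) for l in y])
    ll_null = _null_loglik(codes)
    if p == 0:
        return LrtResult(0.0, 0, 1.0, n, K, 0, dropped_predictors=dropped)
    n_params = (K - 1) * (p + 1)
    if n <= n_params:
        return LrtResult(None, None, None, n, K, p, dropped_predictors=dropped,
                         skipped_reason="insufficient n")
    Xd = sm.add_constant(X, has_constant="add")
    ll_full = None
    converged = True
    flagged = False
    try:
        with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(codes, Xd).fit(method="newton", maxiter=maxiter, disp=0)
            if fit.mle_retvals.get("converged", False) and np.isfinite(fit.llf):
                ll_full = float(fit.llf)
            else:
                converged = False
    except Exception:
        converged = False
    if ll_full is None:
        # bounded-iteration ridge fallback for separable / ill-conditioned fits
        flagged = True
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Z = (X - mu) / sd
        clf = LogisticRegression(C=1e2, max_iter=500).fit(Z, codes)
        proba = clf.predict_proba(Z)
        ll_full = float(np.sum(np.log(proba[np.arange(n), codes])))
    lr = max(0.0, 2.0 * (ll_full - ll_null))
    df = (K - 1) * p
    pvalue = float(stats.chi2.sf(lr, df))
    return LrtResult(lr, df, pvalue, n, K, p, converged=converged, flagged=flagged,
                     dropped_predictors=dropped)


# ---------------------------------------------------------------------------
# Regression grids


def regression_grid(
    predictors: dict[str, np.ndarray],
    table: AnnotationTable,
    patients: list[str] | None = None,
    domains: tuple[str, ...] = ("quality", "range", "subtype"),
    column: str = "feature_kind",
) -> pd.DataFrame:
    """LR tests of each named predictor block against each rater x domain.

    ``predictors`` maps a name (feature kind or face region) to an (n, p)
    matrix aligned with ``patients``.  Returns one row per rater x domain x
    predictor with the LR statistic, df, p-value and any skipped reason.
    """
    patients = patients or table.patients()
    rows = []
    for domain in domains:
        for rater in table.raters():
            y = table.labels_for(rater, domain, patients)
            for name, X in predictors.items():
                X = np.asarray(X, dtype=float)
                if X.ndim == 1:
                    X = X[:, None]
                if len(X) != len(patients):
                    raise ValueError(f"predictor {name!r} not aligned with patients")
                res = multinomial_lrt(X, y, class_order=DOMAINS[domain])
                rows.append(
                    {
                        "rater_id": rater,
                        "domain": domain,
                        column: name,
                        "lr_statistic": res.statistic,
                        "df": res.df,
                        "pvalue": res.pvalue,
                        "flagged": res.flagged,
                        "skipped_reason": res.skipped_reason,
                    }
                )
    return pd.DataFrame(rows)


def facepart_analysis(
    series_by_patient: dict[str, CellIntensitySeries],
    partition: FacePartition,
    table: AnnotationTable,
    domains: tuple[str, ...] = ("quality", "range", "subtype"),
    regions: tuple[str, ...] = REGION_NAMES,
) -> pd.DataFrame:
    """Motion-feature LR tests for each facial region (parts and groups).

    For every region the motion feature (SD of the per-frame mean gray level
    over the region's cells) is computed per patient and tested against each
    rater's labels per domain.  Empty regions are skipped with a reason.
    """
    patients = sorted(series_by_patient)
    predictors: dict[str, np.ndarray] = {}
    empty = []
    for region in regions:
        cells = partition.cells(region)
        if not cells:
            empty.append(region)
            continue
        predictors[region] = np.array(
            [motion_feature(series_by_patient[p], cells, part=region).values[0]
             for p in patients]
        )[:, None]
    grid = regression_grid(predictors, table, patients, domains, column="face_part")
    for region in empty:
        for domain in domains:
            for rater in table.raters():
                grid.loc[len(grid)] = {
                    "rater_id": rater, "domain": domain, "face_part": region,
                    "lr_statistic": None, "df": None, "pvalue": None,
                    "flagged": False, "skipped_reason": "empty region",
                }
    order = {r: i for i, r in enumerate(regions)}
    return (
        grid.sort_values(["domain", "rater_id", "face_part"],
                         key=lambda s: s.map(order) if s.name == "face_part" else s)
        .reset_index(drop=True)
    )
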