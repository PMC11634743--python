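"""PSM-level quantitative processing for the senescence surfaceome pipeline.

Proteins are quantified by peptide-spectral-match (PSM) counts per sample.
This module carries a PSM matrix from raw (possibly incomplete) quantities
to the derived representations the downstream analyses consume:

- chained-equations imputation of missing replicate values,
- z-scores normalized against the matched non-senescent control group,
- a signed log10 compression of z-scores for visualization/clustering,
- PCA and Pearson correlation of condition profiles,
- fuzzy c-means soft clustering of expression trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

CONDITIONS = ("SEN", "CTRL")

__all__ = [
    "PsmMatrix",
    "ZScoreMatrix",
    "ClusterResult",
    "impute_missing",
    "control_zscores",
    "signed_log10",
    "inverse_signed_log10",
    "pearson_matrix",
    "run_pca",
    "fuzzy_cmeans",
]


@dataclass
class PsmMatrix:
    """Protein x sample PSM quantities plus the sample design.

    ``values`` is a proteins-by-samples DataFrame of nonnegative reals; NaN
    marks a missing quantification (distinct from an observed zero).
    ``design`` is indexed by sample id with columns ``cell_model``,
    ``inducer``, ``condition`` (SEN or CTRL), ``replicate`` and optionally
    ``species``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.design.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("values columns must match design sample ids")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        sizes = self.design.groupby(
            ["cell_model", "inducer", "condition"], sort=False
        ).size()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"condition groups with <2 replicates: {small}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("PSM values must be nonnegative where present")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def comparisons(self) -> list[tuple[str, str]]:
        """Distinct (cell_model, inducer) strata, in design order."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.design.iterrows():
            seen.setdefault((row["cell_model"], row["inducer"]), None)
        return list(seen)

    def samples_of(self, cell_model: str, inducer: str, condition: str) -> list[str]:
        d = self.design
        mask = (
            (d["cell_model"] == cell_model)
            & (d["inducer"] == inducer)
            & (d["condition"] == condition)
        )
        return list(d.index[mask])


@dataclass
class ZScoreMatrix:
    """Protein x condition control-normalized z-scores.

    Each column is a (cell_model, inducer, condition) summary (mean over that
    condition's technical replicates of the per-sample z-scores); ``reference``
    maps every column to the control group it was normalized against.
    """

    z: pd.DataFrame
    reference: dict[str, str] = field(default_factory=dict)


@dataclass
class ClusterResult:
    memberships: pd.DataFrame  # protein x cluster, rows sum to 1
    centroids: np.ndarray  # cluster x condition
    c: int
    m: float
    converged: bool
    iterations: int
    objective_path: list[float] = field(default_factory=list)


def impute_missing(
    matrix: PsmMatrix,
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 0,
) -> PsmMatrix:
    """Fill missing PSM entries by chained-equations regression.

    Each sample column with missing values is regressed (ordinary least
    squares) on the other sample columns over the proteins, initialized at
    column means and iterated round-robin until the largest change falls
    below ``tol`` (relative to the data scale) or ``max_iter`` passes.
    Observed entries are never altered; imputed entries are clamped to >= 0.
    """
    values = matrix.values
    all_missing = values.index[values.isna().all(axis=1)]
    if len(all_missing):
        raise ValueError(
            "proteins with no observed values (pre-filter them): "
            + ", ".join(map(str, all_missing[:20]))
        )
    few = values.index[values.notna().sum(axis=1) < 2]
    if len(few):
        warnings.warn(
            f"{len(few)} proteins have <2 observed values; imputation for "
            "them rests on column means alone",
            stacklevel=2,
        )
    if matrix.n_missing == 0:
        return PsmMatrix(values.copy(), matrix.design.copy())

    imputer = IterativeImputer(
        estimator=LinearRegression(),
        max_iter=max_iter,
        tol=tol,
        initial_strategy="mean",
        imputation_order="ascending",
        min_value=0.0,
        random_state=seed,
        sample_posterior=False,
    )
    filled = imputer.fit_transform(values.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    # guarantee the observed entries are bit-identical
    out = out.where(values.isna(), values)
    return PsmMatrix(out, matrix.design.copy())


def _sd_floor(protein_means: np.ndarray) -> np.ndarray:
    # prevents division by zero for constant control replicates
    return 1e-8 * (protein_means + 1.0)


def control_zscores(matrix: PsmMatrix) -> ZScoreMatrix:
    """z-scores of PSMs relative to the matched non-senescent control group.

    For every (cell_model, inducer) stratum, each sample value is centered
    and scaled by the mean and sd of that stratum's CTRL replicates (per
    protein, sd floored to keep results finite); the per-condition column is
    the mean over the condition's technical replicates.
    """
    if matrix.n_missing:
        raise ValueError("control_zscores requires a complete (imputed) matrix")
    cols: dict[str, np.ndarray] = {}
    reference: dict[str, str] = {}
    for cell_model, inducer in matrix.comparisons():
        ctrl = matrix.samples_of(cell_model, inducer, "CTRL")
        if not ctrl:
            raise ValueError(f"stratum ({cell_model}, {inducer}) has no CTRL samples")
        ctrl_vals = matrix.values[ctrl].to_numpy(dtype=float)
        mu = ctrl_vals.mean(axis=1)
        sd = np.maximum(ctrl_vals.std(axis=1, ddof=1), _sd_floor(mu))
        ref_id = f"{cell_model}|{inducer}|CTRL"
        for condition in CONDITIONS:
            samples = matrix.samples_of(cell_model, inducer, condition)
            if not samples:
                continue
            v = matrix.values[samples].to_numpy(dtype=float)
            z = (v - mu[:, None]) / sd[:, None]
            col = f"{cell_model}|{inducer}|{condition}"
            cols[col] = z.mean(axis=1)
            reference[col] = ref_id
    z = pd.DataFrame(cols, index=matrix.protein_ids)
    return ZScoreMatrix(z=z, reference=reference)


def signed_log10(z):
    """Odd, monotone log compression: sign(z) * log10(|z| + 1).

    Continuous through zero (0 -> 0) so that up- and downregulated proteins
    are treated symmetrically; invertible via :func:`inverse_signed_log10`.
    """
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.log10(np.abs(z) + 1.0)
    return out if out.ndim else float(out)


def inverse_signed_log10(y):
    y = np.asarray(y, dtype=float)
    out = np.sign(y) * (np.power(10.0, np.abs(y)) - 1.0)
    return out if out.ndim else float(out)


def pearson_matrix(z: ZScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    """Condition x condition Pearson correlation over proteins."""
    data = z.z if isinstance(z, ZScoreMatrix) else z
    if data.shape[0] < 3:
        raise ValueError("need >=3 proteins for a correlation matrix")
    sds = data.std(axis=0, ddof=0)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")
    r = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=data.columns, columns=data.columns)


def run_pca(
    values: pd.DataFrame | np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of condition profiles with a deterministic sign convention.

    Columns are mean-centered internally. Returns (scores, loadings,
    variance_explained) with loadings of shape (n_components, n_features).
    Each component's sign is fixed so its largest-magnitude loading is
    positive, making repeated runs identical.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("PCA needs a 2-D matrix with >=2 rows and columns")
    k = n_components if n_components is not None else min(X.shape)
    if k > min(X.shape):
        raise ValueError("n_components exceeds matrix dimensions")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return scores, loadings, pca.explained_variance_ratio_


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def fuzzy_cmeans(
    profiles: pd.DataFrame | np.ndarray,
    c: int,
    m: float = 1.25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    standardize: bool = True,
) -> ClusterResult:
    """Fuzzy c-means soft clustering of expression profiles.

    Standard alternating updates: centroids are membership**m weighted means
    and memberships follow the inverse-squared-distance ratio rule with
    exponent 1/(m-1). Profiles are standardized per protein (mean 0, sd 1
    across conditions) before clustering unless ``standardize=False``. A
    profile sitting exactly on a centroid receives membership 1 for that
    cluster (lowest cluster index wins on ties). Convergence is declared
    when the largest membership change drops below ``tol``.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c < 1:
        raise ValueError("cluster count c must be >= 1")
    index = profiles.index if isinstance(profiles, pd.DataFrame) else None
    X = np.asarray(profiles, dtype=float)
    if standardize:
        X = _standardize_rows(X)
    n = X.shape[0]
    distinct = np.unique(X, axis=0).shape[0]
    if c > distinct:
        raise ValueError(f"c={c} exceeds the {distinct} distinct profiles")

    if c == 1:
        u = np.ones((n, 1))
        centroid = X.mean(axis=0, keepdims=True)
        return ClusterResult(
            memberships=pd.DataFrame(u, index=index, columns=[0]),
            centroids=centroid,
            c=1,
            m=m,
            converged=True,
            iterations=0,
            objective_path=[float(((X - centroid) ** 2).sum())],
        )

    rng = np.random.default_rng(seed)
    # seed centroids at c distinct observed profiles
    uniq, first_idx = np.unique(X, axis=0, return_index=True)
    pick = rng.choice(len(uniq), size=c, replace=False)
    centroids = uniq[np.sort(pick)]

    u = _memberships(X, centroids, m)
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = u**m
        centroids = (w.T @ X) / w.sum(axis=0)[:, None]
        u_new = _memberships(X, centroids, m)
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        path.append(float((u_new**m * d2).sum()))
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            converged = True
            break
        u = u_new
    return ClusterResult(
        memberships=pd.DataFrame(u, index=index, columns=range(c)),
        centroids=centroids,
        c=c,
        m=m,
        converged=converged,
        iterations=it,
        objective_path=path,
    )


def _memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = np.zeros_like(d2)
    zero_rows = (d2 <= 0).any(axis=1)
    if zero_rows.any():
        hit = np.argmax(d2[zero_rows] <= 0, axis=1)  # lowest index wins
        u[np.flatnonzero(zero_rows), hit] = 1.0
    ok = ~zero_rows
    if ok.any():
        ratio = d2[ok][:, :, None] / d2[ok][:, None, :]
        u[ok] = 1.0 / (ratio ** (1.0 / (m - 1.0))).sum(axis=2)
    return u
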