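"""Single-cell co-expression validation of candidate senescence markers.

Droplet single-cell counts are binarized (1 = the gene is detected in the
cell), and within each (tissue, cell type) unit the analysis asks two
questions: (i) does the fraction of gene-positive cells increase from young
to old animals, and (ii) do candidate genes co-occur with the senescence
marker CDKN2A (p16) in the same cells, quantified by the log-odds ratio of
the 2x2 presence table with a two-sided Fisher exact p-value against
OR = 1. Zero cells receive the Haldane-Anscombe 0.5 correction so log-odds
stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SingleCellBinary",
    "binarize",
    "assign_age_groups",
    "exclude_unbalanced_tissues",
    "merge_datasets",
    "fraction_positive",
    "flag_age_increase",
    "overlap_flags",
    "compute_lor",
    "lor_table",
    "fisher_exact_p",
]


@dataclass
class SingleCellBinary:
    """Cell x gene binary calls with per-cell metadata.

    ``calls``: DataFrame indexed by cell id, columns = genes, values in
    {0, 1}. ``obs``: DataFrame indexed by the same cell ids with columns
    ``tissue``, ``cell_type`` and ``age_group`` and/or ``age_months``.
    (tissue, cell_type) pairs are the analysis units.
    """

    calls: pd.DataFrame
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.obs.index):
            raise ValueError("calls and obs must be indexed by the same cells")
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate cell ids")
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("calls must be binary")
        for col in ("tissue", "cell_type"):
            if col not in self.obs.columns:
                raise ValueError(f"obs lacks required column {col!r}")

    @property
    def genes(self) -> pd.Index:
        return self.calls.columns

    def units(self) -> list[tuple[str, str]]:
        pairs = self.obs[["tissue", "cell_type"]].drop_duplicates()
        return list(map(tuple, pairs.to_numpy()))

    def n_units(self) -> int:
        return len(self.units())

    def n_tissues(self) -> int:
        return self.obs["tissue"].nunique()

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.calls.to_numpy(dtype=np.int8),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.calls.columns),
        )

    @classmethod
    def from_anndata(cls, adata) -> "SingleCellBinary":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        calls = pd.DataFrame(
            np.asarray(X), index=adata.obs_names, columns=adata.var_names
        )
        return binarize(calls, adata.obs.copy())


def binarize(counts: pd.DataFrame, obs: pd.DataFrame) -> SingleCellBinary:
    """Presence/absence calls: 1 iff count > 0 (idempotent on binary input)."""
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    calls = pd.DataFrame(
        (arr > 0).astype(np.int8), index=counts.index, columns=counts.columns
    )
    return SingleCellBinary(calls=calls, obs=obs)


def assign_age_groups(
    obs: pd.DataFrame, young_max: float = 3.0, old_min: float = 18.0
) -> pd.DataFrame:
    """Label cells young (age <= 3 months) or old (age >= 18 months).

    Cells with intermediate ages are dropped (their count is logged);
    pre-labeled cells without an age pass through unchanged.
    """
    obs = obs.copy()
    if "age_group" not in obs.columns:
        obs["age_group"] = pd.NA
    has_label = obs["age_group"].isin(["young", "old"])
    has_age = "age_months" in obs.columns and obs["age_months"].notna()
    if isinstance(has_age, bool):  # no age column at all
        has_age = pd.Series(False, index=obs.index)
    orphan = ~has_label & ~has_age
    if orphan.any():
        raise ValueError(
            f"{int(orphan.sum())} cells have neither age_months nor age_group"
        )
    need = ~has_label & has_age
    if "age_months" in obs.columns and need.any():
        age = obs.loc[need, "age_months"].astype(float)
        group = pd.Series(pd.NA, index=age.index, dtype=object)
        group[age <= young_max] = "young"
        group[age >= old_min] = "old"
        obs.loc[need, "age_group"] = group
    dropped = obs["age_group"].isna()
    if dropped.any():
        warnings.warn(
            f"excluding {int(dropped.sum())} cells with intermediate ages",
            stacklevel=2,
        )
    return obs[~dropped]


def exclude_unbalanced_tissues(data: SingleCellBinary) -> SingleCellBinary:
    """Drop tissues represented in only one age group."""
    groups = data.obs.groupby("tissue")["age_group"].agg(lambda s: set(s))
    bad = [t for t, gs in groups.items() if not {"young", "old"} <= gs]
    if bad:
        warnings.warn(f"excluding unbalanced tissues: {sorted(bad)}", stacklevel=2)
    keep = ~data.obs["tissue"].isin(bad)
    return SingleCellBinary(data.calls.loc[keep], data.obs.loc[keep])


def merge_datasets(d1: SingleCellBinary, d2: SingleCellBinary) -> SingleCellBinary:
    """Union of cells over the shared gene vocabulary."""
    if len(d2.obs) == 0:
        return d1
    if len(d1.obs) == 0:
        return d2
    dup = d1.calls.index.intersection(d2.calls.index)
    if len(dup):
        raise ValueError(f"duplicate cell ids across datasets: {list(dup[:5])}")
    shared = d1.genes.intersection(d2.genes)
    if len(shared) < max(len(d1.genes), len(d2.genes)):
        warnings.warn(
            f"gene vocabularies differ; using the {len(shared)}-gene intersection",
            stacklevel=2,
        )
    obs_cols = d1.obs.columns.intersection(d2.obs.columns)
    return SingleCellBinary(
        calls=pd.concat([d1.calls[shared], d2.calls[shared]]),
        obs=pd.concat([d1.obs[obs_cols], d2.obs[obs_cols]]),
    )


def fraction_positive(data: SingleCellBinary, gene: str) -> pd.DataFrame:
    """Fraction of gene-positive cells per (tissue, cell_type, age_group)."""
    if gene not in data.calls.columns:
        raise KeyError(f"gene {gene!r} not in vocabulary")
    df = data.obs[["tissue", "cell_type", "age_group"]].copy()
    df["positive"] = data.calls[gene].to_numpy()
    grouped = (
        df.groupby(["tissue", "cell_type", "age_group"], observed=True)["positive"]
        .agg(n_positive="sum", n_total="size")
        .reset_index()
    )
    grouped["gene"] = gene
    grouped["fraction"] = grouped["n_positive"] / grouped["n_total"]
    return grouped


def flag_age_increase(fractions: pd.DataFrame, gene: str | None = None) -> pd.Series:
    """True per (tissue, cell_type) iff fraction_old > fraction_young (strict).

    Units lacking either age group are omitted with a warning.
    """
    f = fractions if gene is None else fractions[fractions["gene"] == gene]
    wide = f.pivot_table(
        index=["tissue", "cell_type"],
        columns="age_group",
        values="fraction",
        aggfunc="first",
        observed=True,
    )
    for col in ("young", "old"):
        if col not in wide.columns:
            wide[col] = np.nan
    incomplete = wide["young"].isna() | wide["old"].isna()
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} units lack one age group; omitted",
            stacklevel=2,
        )
    wide = wide[~incomplete]
    return (wide["old"] > wide["young"]).rename("age_increase")


def overlap_flags(flags_gene: pd.Series, flags_reference: pd.Series) -> dict:
    """Overlap of flagged units between a gene and a reference gene.

    Percent is relative to the gene's flagged-unit count, matching how the
    candidate/CDKN2A overlaps are reported.
    """
    from .dep import percent

    common = flags_gene.index.intersection(flags_reference.index)
    g = flags_gene.loc[common].astype(bool)
    r = flags_reference.loc[common].astype(bool)
    n_gene = int(g.sum())
    n_both = int((g & r).sum())
    return {
        "n_units": len(common),
        "n_gene_flagged": n_gene,
        "n_reference_flagged": int(r.sum()),
        "n_both": n_both,
        "pct_of_gene_flagged": percent(n_both, n_gene, 1) if n_gene else 0.0,
    }


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability convention: the p-value sums the probabilities of all
    tables with the observed margins that are no more probable than the
    observed table.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be nonnegative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def compute_lor(
    data: SingleCellBinary,
    gene1: str,
    gene2: str,
    unit: tuple[str, str],
    log_base: float = math.e,
) -> dict:
    """Co-expression log-odds ratio of two genes within one unit.

    Cells of both age groups are pooled. 2x2 counts: a = both genes
    positive, b = gene1 only, c = gene2 only, d = neither. When any cell is
    zero the Haldane-Anscombe correction (add 0.5 to every cell) is applied
    before taking the log; the Fisher p is always computed on the raw
    counts. Degenerate margins (a gene constant within the unit) are
    flagged.
    """
    for g in (gene1, gene2):
        if g not in data.calls.columns:
            raise KeyError(f"gene {g!r} not in vocabulary")
    tissue, cell_type = unit
    mask = (data.obs["tissue"] == tissue) & (data.obs["cell_type"] == cell_type)
    if not mask.any():
        raise ValueError(f"unit {unit} has no cells")
    g1 = data.calls.loc[mask, gene1].to_numpy(dtype=bool)
    g2 = data.calls.loc[mask, gene2].to_numpy(dtype=bool)
    a = int((g1 & g2).sum())
    b = int((g1 & ~g2).sum())
    c = int((~g1 & g2).sum())
    d = int((~g1 & ~g2).sum())
    corrected = min(a, b, c, d) == 0
    kappa = 0.5 if corrected else 0.0
    lor = math.log((a + kappa) * (d + kappa) / ((b + kappa) * (c + kappa)))
    if log_base != math.e:
        lor /= math.log(log_base)
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    return {
        "tissue": tissue,
        "cell_type": cell_type,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "lor": lor,
        "p_value": fisher_exact_p(a, b, c, d),
        "corrected": corrected,
        "degenerate": degenerate,
    }


def lor_table(
    data: SingleCellBinary, marker: str, candidates, log_base: float = math.e
) -> pd.DataFrame:
    """LOR of the marker vs every candidate over all units (Figure-6-style)."""
    rows = []
    for unit in data.units():
        for gene in candidates:
            rec = compute_lor(data, gene, marker, unit, log_base=log_base)
            rec["gene"] = gene
            rec["marker"] = marker
            rows.append(rec)
    return pd.DataFrame(rows)
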