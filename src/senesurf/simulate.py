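"""Synthetic data with known ground truth for the surfaceome pipeline.

The generator emulates the statistical structure the analysis assumes:
label-free PSM quantities with three technical replicates per condition,
log-normal latent abundances with multiplicative replicate noise, planted
fold changes of at least 1.5, missing replicate values, GO-style surface
flags, a human/mouse homolog map, an 11-tissue expression atlas with
designated low-in-all-tissues genes, published-signature gene sets, a
5-category ligand-receptor catalog, and binarized single-cell expression
with configurable young/old positive fractions and marker/candidate odds
ratios. Everything is reproducible from one master seed: per-stage child
seeds are derived with numpy's SeedSequence(master, spawn_key=(stage,)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .funnel import LR_CATEGORIES, AnnotationBundle
from .psm import PsmMatrix
from .sc import SingleCellBinary

# study-shaped default design: 3 human + 5 mouse senescence comparisons
DEFAULT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("NHLF", "ETO"),
    ("NHLF", "H2O2"),
    ("HUVEC", "H2O2"),
    ("MEF", "ETO"),
    ("MEF", "H2O2"),
    ("AST", "ETO"),
    ("AST", "H2O2"),
    ("AST", "EPO"),
)
SPECIES_OF_MODEL = {
    "NHLF": "human",
    "HUVEC": "human",
    "MEF": "mouse",
    "AST": "mouse",
}
TISSUES = (
    "brain",
    "heart",
    "lung",
    "liver",
    "kidney",
    "spleen",
    "muscle",
    "pancreas",
    "intestine",
    "skin",
    "testis",
)

STAGE_TRUTH, STAGE_PSM, STAGE_BUNDLE, STAGE_SC = 0, 1, 2, 3

__all__ = [
    "DEFAULT_CONDITIONS",
    "SPECIES_OF_MODEL",
    "ProteomicsSimConfig",
    "ScSimConfig",
    "GroundTruth",
    "generate_psm_dataset",
    "generate_annotation_bundle",
    "generate_sc_dataset",
    "joint_success_prob",
    "child_rng",
    "qualify",
]


def child_rng(master_seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(stage,))
    )


def qualify(gene: str, species: str) -> str:
    """Species-qualified protein id ('HS_' human, 'MM_' mouse)."""
    prefix = {"human": "HS_", "mouse": "MM_"}[species]
    return prefix + gene


@dataclass(frozen=True)
class ProteomicsSimConfig:
    seed: int = 0
    n_proteins: int = 2000
    conditions: tuple[tuple[str, str], ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    frac_dep: float = 0.2
    planted_log2fc: tuple[float, float] = (1.0, 3.0)  # |log2FC| range
    cv_technical: float = 0.2
    missing_rate: float = 0.10
    missing_mechanism: str = "random"  # or "intensity"
    frac_surface: float = 0.32
    homolog_coverage: float = 0.93
    frac_low_tissue: float = 0.05
    p_dep_per_condition: float = 0.5  # perturbation prob per comparison for DEP genes
    p_down_given_dep: float = 0.3
    integer_psm: bool = False
    species_of_model: dict = field(
        default_factory=lambda: dict(SPECIES_OF_MODEL), hash=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for name in ("frac_dep", "missing_rate", "frac_surface", "homolog_coverage",
                     "frac_low_tissue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.planted_log2fc[0] < math.log2(1.5) - 1e-12:
            raise ValueError("planted |log2FC| must be >= log2(1.5)")
        if self.missing_mechanism not in ("random", "intensity"):
            raise ValueError("missing_mechanism must be 'random' or 'intensity'")
        for model, _ in self.conditions:
            if model not in self.species_of_model:
                raise ValueError(f"no species assigned to cell model {model!r}")

    def comparison_ids(self) -> list[str]:
        return [f"{m}|{i}" for m, i in self.conditions]


@dataclass(frozen=True)
class ScSimConfig:
    seed: int = 0
    tissue_cell_types: tuple[tuple[str, str], ...] = (
        ("lung", "dendritic cell"),
        ("lung", "fibroblast"),
        ("kidney", "plasma cell"),
        ("spleen", "B cell"),
        ("brain", "pericyte"),
        ("brain", "microglia"),
    )
    n_cells_young: int = 500
    n_cells_old: int = 500
    marker_gene: str = "CDKN2A"
    candidate_genes: tuple[str, ...] = ("PLXNA1", "PLXNA3", "PTK7", "CYB5R1")
    p_young: float | dict = 0.05
    p_old: float | dict = 0.15
    target_or: float | dict = 2.0

    def __post_init__(self) -> None:
        if self.n_cells_young < 1 or self.n_cells_old < 1:
            raise ValueError("cell counts must be >= 1")

    def prob(self, which: str, gene: str, unit: tuple[str, str]) -> float:
        p = self.p_young if which == "young" else self.p_old
        v = _lookup(p, gene, unit)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v} out of [0, 1]")
        return v

    def odds_ratio(self, gene: str, unit: tuple[str, str]) -> float:
        v = _lookup(self.target_or, gene, unit)
        if v <= 0:
            raise ValueError("target_or must be > 0")
        return v


def _lookup(param, gene, unit):
    if isinstance(param, dict):
        for key in ((gene, unit), gene, unit):
            if key in param:
                return float(param[key])
        return float(param["default"])
    return float(param)


@dataclass
class GroundTruth:
    """Planted labels from which every downstream expectation is derivable."""

    dep_labels: pd.DataFrame | None = None  # gene x comparison_id in {up,down,null}
    planted_log2fc: pd.DataFrame | None = None  # signed, 0 where null
    surface_labels: pd.Series | None = None  # bool per latent gene
    homolog_pairs: list | None = None  # (HS_ id, MM_ id)
    low_tissue_genes: set | None = None  # latent gene ids
    signature_genes: dict | None = None  # name -> frozenset of HS_ ids
    expected_candidates: set | None = None  # HS_ ids surviving the funnel
    true_fractions: pd.DataFrame | None = None  # unit x age x gene marginals
    true_or: pd.DataFrame | None = None  # unit x gene target odds ratios

    def to_dep_tables(self, config: ProteomicsSimConfig) -> dict[str, pd.DataFrame]:
        """Noise-free species-qualified DepTables mirroring the planted labels."""
        tables = {}
        for (model, inducer) in config.conditions:
            cid = f"{model}|{inducer}"
            species = config.species_of_model[model]
            labels = self.dep_labels[cid]
            lfc = self.planted_log2fc[cid]
            is_dep = labels != "null"
            tables[cid] = pd.DataFrame(
                {
                    "protein_id": [qualify(g, species) for g in labels.index],
                    "comparison_id": cid,
                    "fc": np.power(2.0, lfc.to_numpy()),
                    "log2fc": lfc.to_numpy(),
                    "p_value": np.where(is_dep, 1e-6, 1.0),
                    "direction": labels.to_numpy(),
                }
            )
            tables[cid].loc[~is_dep.to_numpy(), "direction"] = "none"
        return tables

    def species_of_comparison(self, config: ProteomicsSimConfig) -> dict[str, str]:
        return {
            f"{m}|{i}": config.species_of_model[m] for m, i in config.conditions
        }


def _plant_truth(config: ProteomicsSimConfig) -> GroundTruth:
    """Deterministic planted labels shared by the PSM and annotation stages."""
    rng = child_rng(config.seed, STAGE_TRUTH)
    genes = [f"G{i:05d}" for i in range(config.n_proteins)]
    cids = config.comparison_ids()

    is_dep = rng.random(config.n_proteins) < config.frac_dep
    labels = pd.DataFrame("null", index=genes, columns=cids, dtype=object)
    lfc = pd.DataFrame(0.0, index=genes, columns=cids)
    lo, hi = config.planted_log2fc
    for gi in np.flatnonzero(is_dep):
        hit = rng.random(len(cids)) < config.p_dep_per_condition
        if not hit.any():
            hit[rng.integers(len(cids))] = True
        for ci in np.flatnonzero(hit):
            down = rng.random() < config.p_down_given_dep
            mag = rng.uniform(lo, hi)
            labels.iat[gi, ci] = "down" if down else "up"
            lfc.iat[gi, ci] = -mag if down else mag

    surface = pd.Series(rng.random(config.n_proteins) < config.frac_surface,
                        index=genes)
    covered = rng.random(config.n_proteins) < config.homolog_coverage
    homolog_pairs = [
        (qualify(g, "human"), qualify(g, "mouse"))
        for g, c in zip(genes, covered)
        if c
    ]
    low_tissue = set(
        np.asarray(genes)[rng.random(config.n_proteins) < config.frac_low_tissue]
    )

    # published signatures enriched in up-regulated genes
    any_up = (labels == "up").any(axis=1)
    signatures = {}
    for name in ("sig_transcriptome_A", "sig_transcriptome_B", "sig_proteome_C"):
        p_in = np.where(any_up, 0.15, 0.02)
        members = np.asarray(genes)[rng.random(config.n_proteins) < p_in]
        signatures[name] = frozenset(qualify(g, "human") for g in members)

    expected = _expected_candidates(
        config, labels, surface, covered, low_tissue, signatures
    )
    return GroundTruth(
        dep_labels=labels,
        planted_log2fc=lfc,
        surface_labels=surface,
        homolog_pairs=homolog_pairs,
        low_tissue_genes=low_tissue,
        signature_genes=signatures,
        expected_candidates=expected,
    )


def _expected_candidates(config, labels, surface, covered, low_tissue, signatures):
    """Funnel expectation computed directly from the planted labels.

    Intentionally a plain re-statement of the funnel rules over the truth
    tables (independent of senesurf.funnel), so end-to-end tests compare two
    separate code paths.
    """
    cids = config.comparison_ids()
    species_of = {
        cid: config.species_of_model[cid.split("|")[0]] for cid in cids
    }
    human_cids = [c for c in cids if species_of[c] == "human"]
    mouse_cids = [c for c in cids if species_of[c] == "mouse"]
    genes = list(labels.index)
    cov = dict(zip(genes, covered))

    expected = set()
    sig_union = set().union(*signatures.values())
    for g in genes:
        if not surface[g]:
            continue
        human_dep = (labels.loc[g, human_cids] != "null").any()
        mouse_dep = (labels.loc[g, mouse_cids] != "null").any()
        if not (human_dep and cov[g]):
            continue
        low = g in low_tissue
        n_up = int((labels.loc[g, cids] == "up").sum())
        funnel_ok = mouse_dep and n_up >= 2 and low
        signature_ok = qualify(g, "human") in sig_union and low
        if funnel_ok or signature_ok:
            expected.add(qualify(g, "human"))
    return expected


def generate_psm_dataset(
    config: ProteomicsSimConfig,
) -> tuple[PsmMatrix, GroundTruth]:
    """Simulate the protein x sample PSM matrix with planted effects.

    Latent log2 abundances are normal; senescent condition means are shifted
    by the planted log2 fold change; replicates carry multiplicative
    log-normal noise with coefficient of variation ``cv_technical``; a
    fraction of entries is masked missing (NaN), never leaving a condition
    group without at least one observed value per protein.
    """
    truth = _plant_truth(config)
    rng = child_rng(config.seed, STAGE_PSM)
    genes = list(truth.dep_labels.index)
    n = len(genes)
    mu = rng.normal(8.2, 1.5, size=n)  # latent log2 abundance, ~300 PSMs median
    sigma = math.sqrt(math.log1p(config.cv_technical**2))  # natural-log sd

    columns, design_rows, blocks = [], [], []
    for model, inducer in config.conditions:
        cid = f"{model}|{inducer}"
        delta = truth.planted_log2fc[cid].to_numpy()
        for condition in ("SEN", "CTRL"):
            mean_log2 = mu + (delta if condition == "SEN" else 0.0)
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, sigma, size=n)
                vals = np.exp2(mean_log2) * np.exp(noise)
                sample_id = f"{model}_{inducer}_{condition}_r{rep}"
                columns.append(sample_id)
                blocks.append(vals)
                design_rows.append(
                    {
                        "sample_id": sample_id,
                        "cell_model": model,
                        "inducer": inducer,
                        "condition": condition,
                        "replicate": rep,
                        "species": config.species_of_model[model],
                    }
                )
    values = pd.DataFrame(
        np.column_stack(blocks), index=genes, columns=columns
    )
    if config.integer_psm:
        values = values.round()
    design = pd.DataFrame(design_rows).set_index("sample_id")

    if config.missing_rate > 0:
        arr = values.to_numpy()
        if config.missing_mechanism == "random":
            mask = rng.random(arr.shape) < config.missing_rate
        else:
            # intensity-dependent left censoring: low values go missing more
            from scipy.stats import rankdata

            ranks = rankdata(arr, axis=None).reshape(arr.shape) / arr.size
            mask = rng.random(arr.shape) < np.clip(
                2.0 * config.missing_rate * (1.0 - ranks), 0.0, 1.0
            )
        # keep >=1 observed value per protein per condition group
        for (_, _, _), idx in design.groupby(
            ["cell_model", "inducer", "condition"], sort=False
        ).groups.items():
            cols = [values.columns.get_loc(s) for s in idx]
            sub = mask[:, cols]
            fully = sub.all(axis=1)
            if fully.any():
                unmask = rng.integers(0, len(cols), size=int(fully.sum()))
                for row, j in zip(np.flatnonzero(fully), unmask):
                    mask[row, cols[j]] = False
        arr = arr.astype(float)
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=genes, columns=columns)

    return PsmMatrix(values=values, design=design), truth


def generate_annotation_bundle(
    config: ProteomicsSimConfig, seed: int | None = None
) -> AnnotationBundle:
    """Reference tables consistent with the planted ground truth.

    Surface flags cover both species-qualified ids of every latent gene;
    the homolog map covers ``homolog_coverage`` of genes; the tissue atlas
    gives designated low genes levels in [0, 0.5) and all others levels
    >= 5, so any threshold between separates them exactly; the L-R catalog
    draws categories with cell adhesion most common and secreted
    protein-ECM least common.
    """
    truth = _plant_truth(config)
    rng = child_rng(config.seed if seed is None else seed, STAGE_BUNDLE)
    genes = list(truth.dep_labels.index)

    flag_rows = {}
    for g in genes:
        flag = bool(truth.surface_labels[g])
        flag_rows[qualify(g, "human")] = flag
        flag_rows[qualify(g, "mouse")] = flag
    surface_flags = pd.Series(flag_rows)

    homolog_map = pd.DataFrame(truth.homolog_pairs, columns=["human_id", "mouse_id"])

    atlas_index = [qualify(g, s) for g in genes for s in ("human", "mouse")]
    low = np.repeat([g in truth.low_tissue_genes for g in genes], 2)
    levels = np.where(
        low[:, None],
        rng.uniform(0.0, 0.5, size=(len(atlas_index), len(TISSUES))),
        5.0 + rng.lognormal(2.0, 1.0, size=(len(atlas_index), len(TISSUES))),
    )
    tissue_atlas = pd.DataFrame(levels, index=atlas_index, columns=list(TISSUES))

    n_lr = 2 * config.n_proteins
    weights = np.array([0.46, 0.17, 0.12, 0.22, 0.03])
    cats = rng.choice(len(LR_CATEGORIES), size=n_lr, p=weights)
    hs = [qualify(g, "human") for g in genes]
    lr_catalog = pd.DataFrame(
        {
            "ligand_id": rng.choice(hs, size=n_lr),
            "receptor_id": rng.choice(hs, size=n_lr),
            "category": [LR_CATEGORIES[i] for i in cats],
        }
    )

    return AnnotationBundle(
        surface_flags=surface_flags,
        homolog_map=homolog_map,
        tissue_atlas=tissue_atlas,
        signatures=dict(truth.signature_genes),
        lr_catalog=lr_catalog,
    )


def joint_success_prob(p1: float, p2: float, odds_ratio: float) -> float:
    """P(X=1, Y=1) for Bernoulli marginals p1, p2 at a given odds ratio.

    With OR = p11*p00 / (p10*p01), p11 solves the quadratic
    (OR-1)*p11**2 - (1 + (OR-1)*(p1+p2))*p11 + OR*p1*p2 = 0
    (the Plackett / Emrich-Piedmonte construction); the root inside the
    Frechet bounds [max(0, p1+p2-1), min(p1, p2)] is taken.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("marginals must be in [0, 1]")
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0) or odds_ratio == 1.0:
        return p1 * p2
    a = odds_ratio - 1.0
    b = 1.0 + a * (p1 + p2)
    disc = b * b - 4.0 * a * odds_ratio * p1 * p2
    if disc < 0:
        raise ValueError(
            f"no feasible joint distribution for p1={p1}, p2={p2}, OR={odds_ratio}"
        )
    root = math.sqrt(disc)
    for cand in ((b - root) / (2 * a), (b + root) / (2 * a)):
        if lo - 1e-12 <= cand <= hi + 1e-12:
            return float(min(max(cand, lo), hi))
    raise ValueError(
        f"no root in Frechet bounds for p1={p1}, p2={p2}, OR={odds_ratio}"
    )


def generate_sc_dataset(config: ScSimConfig) -> tuple[SingleCellBinary, GroundTruth]:
    """Binarized single-cell data with planted marker/candidate odds ratios.

    Within each (tissue, cell_type) unit and age group, the marker gene is
    Bernoulli with the configured marginal and each candidate is drawn
    conditionally on the marker so that the pair's joint 2x2 distribution
    hits the target odds ratio exactly (candidates are conditionally
    independent given the marker). Young cells get ages 1-3 months, old
    cells 18-24 months.
    """
    rng = child_rng(config.seed, STAGE_SC)
    genes = [config.marker_gene, *config.candidate_genes]
    call_blocks, obs_rows = [], []
    frac_rows, or_rows = [], []

    for unit in config.tissue_cell_types:
        tissue, cell_type = unit
        for age_group, n_cells in (
            ("young", config.n_cells_young),
            ("old", config.n_cells_old),
        ):
            pm = config.prob(age_group, config.marker_gene, unit)
            marker = rng.random(n_cells) < pm
            cols = {config.marker_gene: marker.astype(np.int8)}
            frac_rows.append(
                {"tissue": tissue, "cell_type": cell_type,
                 "age_group": age_group, "gene": config.marker_gene, "p": pm}
            )
            for gene in config.candidate_genes:
                pc = config.prob(age_group, gene, unit)
                omega = config.odds_ratio(gene, unit)
                p11 = joint_success_prob(pm, pc, omega)
                p_given1 = p11 / pm if pm > 0 else 0.0
                p_given0 = (pc - p11) / (1.0 - pm) if pm < 1 else 0.0
                u = rng.random(n_cells)
                cols[gene] = np.where(
                    marker, u < p_given1, u < p_given0
                ).astype(np.int8)
                frac_rows.append(
                    {"tissue": tissue, "cell_type": cell_type,
                     "age_group": age_group, "gene": gene, "p": pc}
                )
            ages = rng.integers(1, 4, n_cells) if age_group == "young" \
                else rng.integers(18, 25, n_cells)
            for i in range(n_cells):
                obs_rows.append(
                    {
                        "cell_id": f"{tissue}|{cell_type}|{age_group}|{i}",
                        "tissue": tissue,
                        "cell_type": cell_type,
                        "age_group": age_group,
                        "age_months": int(ages[i]),
                    }
                )
            call_blocks.append(pd.DataFrame(cols))
        for gene in config.candidate_genes:
            or_rows.append(
                {"tissue": tissue, "cell_type": cell_type, "gene": gene,
                 "target_or": config.odds_ratio(gene, unit)}
            )

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    calls = pd.concat(call_blocks, ignore_index=True)[genes]
    calls.index = obs.index
    data = SingleCellBinary(calls=calls, obs=obs)
    truth = GroundTruth(
        true_fractions=pd.DataFrame(frac_rows),
        true_or=pd.DataFrame(or_rows),
    )
    return data, truth
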