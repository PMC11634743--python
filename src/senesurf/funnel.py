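"""Cross-species candidate-prioritization funnel.

Senotherapeutic candidate surface proteins are prioritized by a sequence of
set reductions: restrict DEPs to GO-annotated surface proteins, aggregate
DEP sets per species, map human ids to murine homologs, intersect the two
species' DEP sets, keep proteins upregulated in at least k senescence
conditions, and finally keep proteins with absent-or-low expression across
vital tissues of both species. A parallel branch intersects the
homolog-mapped human DEPs with published senescence signatures; candidates
are the union of both branches' tissue-filtered survivors. Every stage only
removes ids, and the full per-stage provenance is recorded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .dep import percent

LR_CATEGORIES = (
    "cell adhesion",
    "ECM-receptor",
    "cytokine-cytokine receptor",
    "secreted protein-receptor",
    "secreted protein-ECM",
)

__all__ = [
    "LR_CATEGORIES",
    "AnnotationBundle",
    "FunnelReport",
    "classify_surface",
    "map_homologs",
    "cross_species_overlap",
    "filter_min_conditions",
    "tissue_expression_filter",
    "signature_overlap",
    "categorize_lr",
    "run_funnel",
    "default_tissue_threshold",
]


@dataclass
class AnnotationBundle:
    """Reference tables consumed by the funnel.

    surface_flags: protein id -> bool (GO plasma membrane / extracellular).
    homolog_map: DataFrame with columns human_id, mouse_id (pairs unique).
    tissue_atlas: gene x tissue nonnegative expression levels.
    signatures: published senescence gene sets by name.
    lr_catalog: ligand-receptor records with a 5-class category label.
    """

    surface_flags: pd.Series
    homolog_map: pd.DataFrame
    tissue_atlas: pd.DataFrame
    signatures: dict[str, frozenset]
    lr_catalog: pd.DataFrame

    def __post_init__(self) -> None:
        if self.homolog_map.duplicated(["human_id", "mouse_id"]).any():
            raise ValueError("homolog_map contains duplicate pairs")
        if (self.tissue_atlas.to_numpy() < 0).any():
            raise ValueError("tissue atlas levels must be nonnegative")
        bad = set(self.lr_catalog["category"]) - set(LR_CATEGORIES)
        if bad:
            raise ValueError(f"unknown L-R categories: {sorted(bad)}")


@dataclass
class FunnelReport:
    stages: list[dict] = field(default_factory=list)  # name, n_in, n_out, ids
    candidates: set[str] = field(default_factory=set)
    provenance: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, ids_in, ids_out) -> None:
        ids_in, ids_out = set(ids_in), set(ids_out)
        if not ids_out <= ids_in:
            raise ValueError(f"stage {name} emitted ids outside its input")
        self.stages.append(
            {
                "name": name,
                "n_in": len(ids_in),
                "n_out": len(ids_out),
                "ids": sorted(ids_out),
            }
        )

    def counts(self) -> dict[str, tuple[int, int]]:
        return {s["name"]: (s["n_in"], s["n_out"]) for s in self.stages}

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "candidates": sorted(self.candidates),
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s["name"], s["n_in"], s["n_out"]) for s in self.stages],
            columns=["stage", "n_in", "n_out"],
        )


def classify_surface(protein_ids, bundle: AnnotationBundle) -> tuple[set[str], float]:
    """Subset of ids flagged surface, and the surface fraction of the input."""
    ids = list(protein_ids)
    if not ids:
        raise ValueError("classify_surface on empty input")
    missing = [i for i in ids if i not in bundle.surface_flags.index]
    if missing:
        warnings.warn(
            f"{len(missing)} ids without a surface flag treated as non-surface",
            stacklevel=2,
        )
    surface = {i for i in ids if bool(bundle.surface_flags.get(i, False))}
    return surface, len(surface) / len(ids)


def map_homologs(
    ids, homolog_map: pd.DataFrame, direction: str = "human_to_mouse"
) -> tuple[list[tuple[str, str]], set[str]]:
    """Translate ids across species; one-to-many mappings kept as pairs."""
    if direction == "human_to_mouse":
        src, dst = "human_id", "mouse_id"
    elif direction == "mouse_to_human":
        src, dst = "mouse_id", "human_id"
    else:
        raise ValueError("direction must be human_to_mouse or mouse_to_human")
    ids = set(ids)
    sub = homolog_map[homolog_map[src].isin(ids)]
    pairs = list(zip(sub[src], sub[dst]))
    unmapped = ids - set(sub[src])
    return pairs, unmapped


def cross_species_overlap(
    human_deps, mouse_deps, homolog_map: pd.DataFrame
) -> set[tuple[str, str]]:
    """Homolog pairs (h, m) with h a human DEP and m a mouse DEP."""
    human_deps, mouse_deps = set(human_deps), set(mouse_deps)
    if not human_deps or not mouse_deps:
        return set()
    sub = homolog_map[
        homolog_map["human_id"].isin(human_deps)
        & homolog_map["mouse_id"].isin(mouse_deps)
    ]
    return set(zip(sub["human_id"], sub["mouse_id"]))


def filter_min_conditions(
    dep_records: pd.DataFrame, k: int = 2, direction: str = "up"
) -> set[str]:
    """Ids with a direction-matching DEP call in >= k distinct comparisons."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = dep_records[dep_records["direction"] == direction]
    counts = hits.groupby("protein_id")["comparison_id"].nunique()
    return set(counts.index[counts >= k])


def tissue_expression_filter(
    ids,
    atlas: pd.DataFrame | list[pd.DataFrame],
    level_threshold: float | None = None,
    fraction_tissues: float = 1.0,
    fail_open: bool = True,
) -> set[str]:
    """Ids with absent-or-low expression across (a fraction of) vital tissues.

    An id passes one atlas when its level is <= level_threshold in at least
    ``fraction_tissues`` of the tissue columns. When several atlases are
    given (one per species) an id must pass every atlas it appears in. The
    default threshold is the 10th percentile of the atlas's nonzero values
    (the original qualitative "low in tissue maps" cut made explicit). Ids
    absent from an atlas pass it with a warning when ``fail_open``.
    """
    atlases = atlas if isinstance(atlas, list) else [atlas]
    ids = set(ids)
    surviving = set(ids)
    for a in atlases:
        if a.shape[1] == 0:
            raise ValueError("tissue atlas has no tissue columns")
        thr = default_tissue_threshold(a) if level_threshold is None else level_threshold
        present = [i for i in ids if i in a.index]
        missing = ids - set(present)
        if missing and not fail_open:
            surviving -= missing
        elif missing:
            warnings.warn(
                f"{len(missing)} ids absent from atlas pass the tissue "
                "filter by fail-open policy",
                stacklevel=2,
            )
        if present:
            sub = a.loc[present]
            frac_low = (sub <= thr).mean(axis=1)
            failed = set(sub.index[frac_low < fraction_tissues])
            surviving -= failed
    return surviving


def default_tissue_threshold(atlas: pd.DataFrame) -> float:
    vals = atlas.to_numpy().ravel()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        return 0.0
    import numpy as np

    return float(np.percentile(nonzero, 10))


def signature_overlap(dep_ids, signatures: dict[str, frozenset]) -> pd.DataFrame:
    """Ids present in >=1 published signature, annotated with the set names."""
    rows = []
    for pid in sorted(set(dep_ids)):
        names = sorted(name for name, s in signatures.items() if pid in s)
        if names:
            rows.append({"protein_id": pid, "signatures": ";".join(names)})
    return pd.DataFrame(rows, columns=["protein_id", "signatures"])


def categorize_lr(dep_ids, lr_catalog: pd.DataFrame) -> pd.DataFrame:
    """Tally ligand-receptor interactions touching the DEP set per category."""
    if lr_catalog.empty:
        raise ValueError("empty ligand-receptor catalog")
    dep_ids = set(dep_ids)
    hit = lr_catalog[
        lr_catalog["ligand_id"].isin(dep_ids) | lr_catalog["receptor_id"].isin(dep_ids)
    ]
    counts = {cat: int((hit["category"] == cat).sum()) for cat in LR_CATEGORIES}
    total = sum(counts.values())
    rows = [
        {
            "category": cat,
            "count": n,
            "proportion": (n / total) if total else float("nan"),
        }
        for cat, n in counts.items()
    ]
    return pd.DataFrame(rows)


def run_funnel(
    dep_tables: dict[str, pd.DataFrame],
    species_of_comparison: dict[str, str],
    bundle: AnnotationBundle,
    k: int = 2,
    level_threshold: float | None = None,
    fraction_tissues: float = 1.0,
    union_rule: str = "funnel_or_signature",
) -> FunnelReport:
    """End-to-end candidate prioritization.

    ``dep_tables`` maps comparison_id -> DepTable whose protein ids are
    species-qualified; ``species_of_comparison`` labels each comparison
    'human' or 'mouse'. Candidates are reported as human ids.
    """
    if union_rule not in ("funnel_or_signature", "funnel_only"):
        raise ValueError("unknown union_rule")
    report = FunnelReport()

    dep_rows = []
    for cid, table in dep_tables.items():
        hit = table[table["direction"] != "none"]
        for pid, d in zip(hit["protein_id"], hit["direction"]):
            dep_rows.append(
                {
                    "protein_id": pid,
                    "comparison_id": cid,
                    "direction": d,
                    "species": species_of_comparison[cid],
                }
            )
    records = pd.DataFrame(
        dep_rows, columns=["protein_id", "comparison_id", "direction", "species"]
    )
    all_dep_ids = set(records["protein_id"])
    if not all_dep_ids:
        report.provenance["note"] = "no DEPs in input"
        return report

    surface, frac = classify_surface(all_dep_ids, bundle)
    report.add_stage("surface", all_dep_ids, surface)
    report.provenance["surface_fraction"] = {"value": frac}
    records = records[records["protein_id"].isin(surface)]

    human_ids = set(records.loc[records["species"] == "human", "protein_id"])
    mouse_ids = set(records.loc[records["species"] == "mouse", "protein_id"])
    report.provenance["per_species"] = {
        "human_deps": len(human_ids),
        "mouse_deps": len(mouse_ids),
    }

    pairs, unmapped = map_homologs(human_ids, bundle.homolog_map, "human_to_mouse")
    mapped_human = {h for h, _ in pairs}
    report.add_stage("homolog_mapped", human_ids, mapped_human)
    report.provenance["homolog"] = {
        "mapped": len(mapped_human),
        "unmapped": len(unmapped),
    }

    overlap_pairs = cross_species_overlap(mapped_human, mouse_ids, bundle.homolog_map)
    overlap_human = {h for h, _ in overlap_pairs}
    report.add_stage("cross_species_overlap", mapped_human, overlap_human)

    # collapse mouse DEP evidence onto the human id of each homolog pair so
    # "up in >= k conditions" counts conditions of both species
    mouse_to_human = {}
    for h, m_ in zip(bundle.homolog_map["human_id"], bundle.homolog_map["mouse_id"]):
        mouse_to_human.setdefault(m_, set()).add(h)
    collapsed = records.copy()
    collapsed["gene"] = [
        pid
        if sp == "human"
        else ";".join(sorted(mouse_to_human.get(pid, {pid})))
        for pid, sp in zip(collapsed["protein_id"], collapsed["species"])
    ]
    collapsed = collapsed.assign(gene=collapsed["gene"].str.split(";")).explode("gene")
    gene_records = collapsed.rename(columns={"gene": "protein_id_gene"})[
        ["protein_id_gene", "comparison_id", "direction"]
    ].rename(columns={"protein_id_gene": "protein_id"})
    up_k = filter_min_conditions(gene_records, k=k, direction="up")
    funnel_upk = overlap_human & up_k
    report.add_stage(f"up_in_ge_{k}_conditions", overlap_human, funnel_upk)

    partners: dict[str, set[str]] = {}
    for h, m_ in overlap_pairs:
        partners.setdefault(h, set()).add(m_)
    check_ids = set(funnel_upk) | set().union(
        *(partners.get(h, set()) for h in funnel_upk), set()
    )
    low_ok = tissue_expression_filter(
        check_ids, bundle.tissue_atlas, level_threshold, fraction_tissues
    )
    # low in both species: the human id and at least one paired mouse homolog
    funnel_surv = {
        h
        for h in funnel_upk
        if h in low_ok and (not partners.get(h) or partners[h] & low_ok)
    }
    report.add_stage("tissue_low", funnel_upk, funnel_surv)

    candidates = set(funnel_surv)
    if union_rule == "funnel_or_signature":
        sig = signature_overlap(mapped_human, bundle.signatures)
        sig_ids = set(sig["protein_id"])
        report.provenance["signature_overlap"] = {"n": len(sig_ids)}
        sig_surv = tissue_expression_filter(
            sig_ids, bundle.tissue_atlas, level_threshold, fraction_tissues
        )
        report.add_stage("signature_branch_tissue_low", sig_ids, sig_surv)
        candidates |= sig_surv

    report.candidates = candidates
    report.provenance["final"] = {
        "n_candidates": len(candidates),
        "pct_of_surface_deps": percent(len(candidates), len(surface), 1)
        if surface
        else 0.0,
    }
    return report
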