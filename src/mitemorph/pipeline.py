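"""End-to-end orchestration of the morphometric analysis.

A study run executes, for each configured analysis block (joint or
per-species scope, with or without allometric components):

    GPA → tangent shape variables → (optional allometry removal) →
    CVA over populations + Mahalanobis/Procrustes distance matrices with
    pairwise permutation tests → leave-one-out classification →
    multivariate dispersion tests → Mantel test against great-circle
    geographic distances.

Specimens from singleton populations are aligned to the fitted consensus
and projected passively into the ordination but take part in no statistic,
so dropping them changes plots only.  All randomness is seeded and every
permutation count is recorded in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import importlib

# the package namespace re-exports same-named callables (e.g. cva), so
# resolve the submodules explicitly
allom_mod = importlib.import_module("mitemorph.allometry")
cva_mod = importlib.import_module("mitemorph.cva")
disp_mod = importlib.import_module("mitemorph.dispersion")
from .landmark_io import LandmarkDataset
from .superimposition import AlignedDataset, gpa, opa_align, tangent_project


@dataclass
class AnalysisConfig:
    """Settings of a full study run."""

    analyses: tuple[tuple[str, str], ...] = (
        ("joint", "with"),
        ("joint", "without"),
        ("per-species", "with"),
        ("per-species", "without"),
    )
    n_perm_pairwise: int = 10_000
    n_perm_dispersion: int = 999
    n_perm_mantel: int = 9_999
    seed: int = 0
    procrustes_kind: str = "full"
    log_size: bool = False

    def __post_init__(self) -> None:
        for scope, allom in self.analyses:
            if scope not in {"joint", "per-species"} or allom not in {"with", "without"}:
                raise ValueError(f"bad analysis block ({scope!r}, {allom!r})")
        if min(self.n_perm_pairwise, self.n_perm_dispersion, self.n_perm_mantel) < 99:
            raise ValueError("permutation counts must be >= 99")


@dataclass
class SpeciesStats:
    """Per-species numbers inside one analysis block."""

    cva: cva_mod.CVAResult
    mean_mahalanobis: float
    mean_procrustes: float
    loo: cva_mod.ClassificationResult
    allometry_pct: float | None = None
    dispersion_populations: disp_mod.DispersionResult | None = None
    pairwise_dispersion_p: tuple[list[str], np.ndarray] | None = None
    mantel: disp_mod.MantelResult | None = None


@dataclass
class AnalysisBlock:
    scope: str
    allometry: str  # "with" | "without"
    species: dict[str, SpeciesStats] = field(default_factory=dict)
    joint_cva: cva_mod.CVAResult | None = None
    joint_loo: cva_mod.ClassificationResult | None = None
    allometry_pct_joint: float | None = None
    cv1_size_r: float | None = None
    dispersion_species: disp_mod.DispersionResult | None = None
    t_mahalanobis: tuple[float, float] | None = None
    t_procrustes: tuple[float, float] | None = None
    passive_scores: np.ndarray | None = None
    passive_ids: list[str] | None = None
    gpa_iterations: int = 0
    gpa_converged: bool = True


@dataclass
class StudyReport:
    blocks: dict[tuple[str, str], AnalysisBlock]
    config: AnalysisConfig
    species_names: list[str]

    def summary(self) -> dict[str, Any]:
        """Flat, JSON-ready digest of the headline numbers."""
        out: dict[str, Any] = {"seed": self.config.seed}
        for (scope, allom), block in self.blocks.items():
            key = f"{scope}_{allom}_allometry".replace("-", "_")
            entry: dict[str, Any] = {}
            if block.allometry_pct_joint is not None:
                entry["allometry_pct_joint"] = block.allometry_pct_joint
            if block.cv1_size_r is not None:
                entry["cv1_size_r"] = block.cv1_size_r
            for sp, st in block.species.items():
                entry[f"mean_mahalanobis_{sp}"] = st.mean_mahalanobis
                entry[f"mean_procrustes_{sp}"] = st.mean_procrustes
                entry[f"loo_pct_correct_{sp}"] = (
                    st.loo.pct_correct_overall if st.loo is not None else None
                )
                if st.allometry_pct is not None:
                    entry[f"allometry_pct_{sp}"] = st.allometry_pct
                if st.mantel is not None:
                    entry[f"mantel_r_{sp}"] = st.mantel.r
                    entry[f"mantel_p_{sp}"] = st.mantel.perm_p
            if block.t_mahalanobis is not None:
                entry["t_test_mahalanobis_p"] = block.t_mahalanobis[1]
            if block.t_procrustes is not None:
                entry["t_test_procrustes_p"] = block.t_procrustes[1]
            if block.dispersion_species is not None:
                entry["dispersion_species_p"] = block.dispersion_species.perm_p
            out[key] = entry
        return out


def _align_with_passive(
    dataset: LandmarkDataset,
) -> tuple[AlignedDataset, np.ndarray, list[str], np.ndarray, np.ndarray]:
    """GPA on the statistically included specimens; singletons are then
    aligned to the fitted consensus by ordinary Procrustes and
    tangent-projected, so they can be shown without influencing anything.

    Returns (aligned, shape_vars, passive_ids, passive_vars, passive_sizes).
    """
    included_ids = [i for i in dataset.specimen_ids if i not in dataset.excluded_from_stats]
    passive_ids = [i for i in dataset.specimen_ids if i in dataset.excluded_from_stats]
    core = dataset.subset(included_ids)
    aligned = gpa(core)
    shape_vars = aligned.shape_variables(tangent=True)

    passive_vars = np.empty((0, shape_vars.shape[1]))
    passive_sizes = np.empty(0)
    if passive_ids:
        sub = dataset.subset(passive_ids)
        coords = sub.coords_array()
        from .superimposition import centroid_size as _cs

        passive_sizes = np.array([_cs(c) for c in coords])
        rows = []
        c_flat = aligned.consensus.reshape(-1)
        c_unit = c_flat / np.linalg.norm(c_flat)
        for c in coords:
            al = opa_align(c, aligned.consensus)[0]
            x = al.reshape(-1)
            rows.append(x + (1.0 - x @ c_unit) * c_unit)
        passive_vars = np.stack(rows)
    return aligned, shape_vars, passive_ids, passive_vars, passive_sizes


def _species_distance_stats(
    cva_res: cva_mod.CVAResult, populations_of_species: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle Mahalanobis and Procrustes distances among one
    species' populations, sliced from a (possibly joint) CVA."""
    idx = [cva_res.group_labels.index(p) for p in populations_of_species]
    sub_m = cva_res.mahalanobis[np.ix_(idx, idx)]
    sub_p = cva_res.procrustes_dist[np.ix_(idx, idx)]
    return cva_mod.upper_triangle(sub_m), cva_mod.upper_triangle(sub_p)


def _loo_pct_by_species(
    loo: cva_mod.ClassificationResult, pop_species: dict[str, str]
) -> dict[str, float]:
    """Percent of each species' specimens correctly classified to their
    population in a joint leave-one-out run."""
    out: dict[str, float] = {}
    labels = loo.group_labels
    for sp in sorted(set(pop_species.values())):
        rows = [i for i, g in enumerate(labels) if pop_species[g] == sp]
        total = loo.confusion[rows].sum()
        correct = sum(loo.confusion[i, i] for i in rows)
        out[sp] = 100.0 * correct / total if total else float("nan")
    return out


def run_full_analysis(
    dataset: LandmarkDataset,
    *,
    latlon: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> StudyReport:
    """Execute every configured analysis block on a labelled dataset."""
    cfg = config or AnalysisConfig()
    species_names = sorted(set(dataset.species_of.values()))
    rng = np.random.default_rng(cfg.seed)
    blocks: dict[tuple[str, str], AnalysisBlock] = {}

    # Joint superimposition (shared by the two joint blocks)
    aligned_j, vars_j, passive_ids, passive_vars, passive_sizes = _align_with_passive(dataset)
    pops_j = aligned_j.populations()
    species_j = aligned_j.species()
    sizes_j = aligned_j.centroid_sizes
    allom_joint = allom_mod.regress_on_size(vars_j, sizes_j, log_size=cfg.log_size)

    # Per-species superimpositions: separate analyses re-run GPA on the
    # species subset rather than slicing the joint fit
    per_species: dict[str, tuple[AlignedDataset, np.ndarray]] = {}
    for sp in species_names:
        ids = [
            i
            for i in dataset.specimen_ids
            if dataset.species_of[i] == sp and i not in dataset.excluded_from_stats
        ]
        sub = dataset.subset(ids)
        al = gpa(sub)
        per_species[sp] = (al, al.shape_variables(tangent=True))

    geo: dict[str, tuple[list[str], np.ndarray]] | None = None
    if latlon is not None:
        geo = {}
        for sp in species_names:
            sp_pops = sorted(
                {g for i, g in dataset.group_of.items() if dataset.species_of[i] == sp
                 and i not in dataset.excluded_from_stats}
            )
            rows = latlon.set_index("population").reindex(sp_pops)
            if not rows[["lat", "lon"]].isna().any().any():
                geo[sp] = (sp_pops, disp_mod.great_circle_matrix(rows[["lat", "lon"]].values))

    for scope, allom in cfg.analyses:
        block = AnalysisBlock(scope=scope, allometry=allom)
        if scope == "joint":
            x = vars_j if allom == "with" else allom_mod.remove_allometry(
                vars_j, sizes_j, log_size=cfg.log_size
            )
            block.allometry_pct_joint = allom_joint.pct_variance_predicted
            block.gpa_iterations = aligned_j.n_iterations
            block.gpa_converged = aligned_j.converged
            joint_cva = cva_mod.cva(
                x,
                pops_j,
                n_perm=cfg.n_perm_pairwise,
                seed=rng,
                procrustes_kind=cfg.procrustes_kind,
            )
            block.joint_cva = joint_cva
            block.cv1_size_r = cva_mod.cv_size_correlation(joint_cva.scores[:, 0], sizes_j)
            loo = cva_mod.loo_classify(x, pops_j)
            block.joint_loo = loo
            pop_species = {
                g: sp for g, sp in zip(pops_j, species_j)
            }
            loo_by_sp = _loo_pct_by_species(loo, pop_species)
            block.dispersion_species = disp_mod.dispersion_test(
                x, species_j, n_perm=cfg.n_perm_dispersion, seed=rng
            )
            dist_sets = {}
            for sp in species_names:
                sp_pops = sorted({g for g, s in pop_species.items() if s == sp})
                dm, dp = _species_distance_stats(joint_cva, sp_pops)
                dist_sets[sp] = (dm, dp)
                # joint confusion matrix, but the headline percentage is
                # this species' share of correctly classified specimens
                st = SpeciesStats(
                    cva=joint_cva,
                    mean_mahalanobis=float(dm.mean()),
                    mean_procrustes=float(dp.mean()),
                    loo=cva_mod.ClassificationResult(
                        group_labels=loo.group_labels,
                        confusion=loo.confusion,
                        pct_correct_per_group=loo.pct_correct_per_group,
                        pct_correct_overall=loo_by_sp[sp],
                    ),
                )
                if geo and sp in geo:
                    sp_pop_list, gmat = geo[sp]
                    idx = [joint_cva.group_labels.index(p) for p in sp_pop_list]
                    mmat = joint_cva.mahalanobis[np.ix_(idx, idx)]
                    if len(sp_pop_list) >= 4:
                        st.mantel = disp_mod.mantel_test(
                            gmat, mmat, n_perm=cfg.n_perm_mantel, seed=rng
                        )
                block.species[sp] = st
            a_sets = dist_sets[species_names[0]]
            b_sets = dist_sets[species_names[1]]
            block.t_mahalanobis = cva_mod.compare_distance_means(a_sets[0], b_sets[0])
            block.t_procrustes = cva_mod.compare_distance_means(a_sets[1], b_sets[1])
            if passive_ids:
                xp = passive_vars
                if allom == "without":
                    # passive specimens get the fitted regression removed too
                    pred = np.outer(passive_sizes, allom_joint.slope_vector)
                    xp = passive_vars - pred - allom_joint.intercept_vector + vars_j.mean(axis=0)
                block.passive_scores = cva_mod.project_passive(joint_cva, xp)
                block.passive_ids = list(passive_ids)
        else:  # per-species
            for sp in species_names:
                al, xv = per_species[sp]
                sizes = al.centroid_sizes
                reg = allom_mod.regress_on_size(xv, sizes, log_size=cfg.log_size)
                x = xv if allom == "with" else allom_mod.remove_allometry(
                    xv, sizes, log_size=cfg.log_size
                )
                res = cva_mod.cva(
                    x,
                    al.populations(),
                    n_perm=cfg.n_perm_pairwise,
                    seed=rng,
                    procrustes_kind=cfg.procrustes_kind,
                )
                loo = cva_mod.loo_classify(x, al.populations())
                labels, pdisp = disp_mod.pairwise_dispersion(
                    x, al.populations(), n_perm=cfg.n_perm_dispersion, seed=rng
                )
                st = SpeciesStats(
                    cva=res,
                    mean_mahalanobis=cva_mod.mean_offdiagonal(res.mahalanobis),
                    mean_procrustes=cva_mod.mean_offdiagonal(res.procrustes_dist),
                    loo=loo,
                    allometry_pct=reg.pct_variance_predicted,
                    dispersion_populations=disp_mod.dispersion_test(
                        x, al.populations(), n_perm=cfg.n_perm_dispersion, seed=rng
                    ),
                    pairwise_dispersion_p=(labels, pdisp),
                )
                if geo and sp in geo and len(geo[sp][0]) >= 4:
                    sp_pop_list, gmat = geo[sp]
                    idx = [res.group_labels.index(p) for p in sp_pop_list]
                    st.mantel = disp_mod.mantel_test(
                        gmat,
                        res.mahalanobis[np.ix_(idx, idx)],
                        n_perm=cfg.n_perm_mantel,
                        seed=rng,
                    )
                block.species[sp] = st
            a = block.species[species_names[0]]
            b = block.species[species_names[1]]
            block.t_mahalanobis = cva_mod.compare_distance_means(
                cva_mod.upper_triangle(a.cva.mahalanobis),
                cva_mod.upper_triangle(b.cva.mahalanobis),
            )
            block.t_procrustes = cva_mod.compare_distance_means(
                cva_mod.upper_triangle(a.cva.procrustes_dist),
                cva_mod.upper_triangle(b.cva.procrustes_dist),
            )
        blocks[(scope, allom)] = block

    return StudyReport(blocks=blocks, config=cfg, species_names=species_names)


# ---------------------------------------------------------------------------
# table exports


def _p_label(p: float) -> str:
    if p < 0.001:
        return "< 0.001"
    if p < 0.005:
        return "< 0.005"
    if p < 0.01:
        return "< 0.01"
    if p < 0.05:
        return "< 0.05"
    return "n.s."


def export_table2(report: StudyReport) -> pd.DataFrame:
    """Mean Mahalanobis and Procrustes distances between populations, per
    species, joint and separate analyses, with t-test p labels (3
    decimals)."""
    sp_a, sp_b = report.species_names[:2]
    rows = []
    for metric in ("mahalanobis", "procrustes"):
        for allom in ("with", "without"):
            row: dict[str, Any] = {"metric": metric, "allometric_effects": allom}
            for scope, tag in (("joint", "joint"), ("per-species", "separate")):
                block = report.blocks.get((scope, allom))
                if block is None:
                    continue
                attr = "mean_mahalanobis" if metric == "mahalanobis" else "mean_procrustes"
                row[f"{tag}_{sp_a}"] = round(getattr(block.species[sp_a], attr), 3)
                row[f"{tag}_{sp_b}"] = round(getattr(block.species[sp_b], attr), 3)
                tt = block.t_mahalanobis if metric == "mahalanobis" else block.t_procrustes
                row[f"{tag}_p"] = _p_label(tt[1])
            rows.append(row)
    return pd.DataFrame(rows)


def export_table3(cva_result: cva_mod.CVAResult, *, star_alpha: float = 0.01) -> pd.DataFrame:
    """Combined-triangle pairwise distance table: Mahalanobis above the
    diagonal (starred when the permutation p is below ``star_alpha``),
    Procrustes below."""
    labels = cva_result.group_labels
    g = len(labels)
    cells = [["" for _ in range(g)] for _ in range(g)]
    for i in range(g):
        for j in range(g):
            if i == j:
                cells[i][j] = "-"
            elif i < j:
                star = (
                    "*"
                    if cva_result.perm_p_mahalanobis is not None
                    and cva_result.perm_p_mahalanobis[i, j] < star_alpha
                    else ""
                )
                cells[i][j] = f"{cva_result.mahalanobis[i, j]:.3f}{star}"
            else:
                star = (
                    "*"
                    if cva_result.perm_p_procrustes is not None
                    and cva_result.perm_p_procrustes[i, j] < star_alpha
                    else ""
                )
                cells[i][j] = f"{cva_result.procrustes_dist[i, j]:.3f}{star}"
    return pd.DataFrame(cells, index=labels, columns=labels)


def write_report_bundle(report: StudyReport, out_dir: str | Path) -> Path:
    """Write tables and the JSON summary of a study run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_table2(report).to_csv(out / "table2_distance_means.csv", index=False)
    for (scope, allom), block in report.blocks.items():
        tag = f"{scope.replace('-', '_')}_{allom}_allometry"
        if block.joint_cva is not None:
            export_table3(block.joint_cva).to_csv(out / f"table3_{tag}.csv")
            pd.DataFrame(
                block.joint_loo.confusion,
                index=block.joint_loo.group_labels,
                columns=block.joint_loo.group_labels,
            ).to_csv(out / f"confusion_{tag}.csv")
        for sp, st in block.species.items():
            if scope == "per-species":
                export_table3(st.cva).to_csv(out / f"table3_{tag}_{sp}.csv")
                pd.DataFrame(
                    st.loo.confusion,
                    index=st.loo.group_labels,
                    columns=st.loo.group_labels,
                ).to_csv(out / f"confusion_{tag}_{sp}.csv")
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report.summary(), indent=2, default=float))
    return summary_path
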