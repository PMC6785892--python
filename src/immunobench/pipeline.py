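"""Pipeline orchestration: filtering, clustering and benchmark output for
the three peptidic dataset branches (Ab-Ag, TCR-pMHC, MHC-ligand) and the
non-peptidic branch.

Quality filters run in a fixed order — resolution, R-free, missing CDR
backbone, length — so attrition accounting is reproducible; the order
does not affect the kept set.  Every stage is deterministic: records are
processed in sorted structure-id order and there is no randomness
anywhere in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .annotation import extract_cdrs, has_missing_cdr_backbone
from .clustering import (ROLE_PREFIX, cluster_antigens, cluster_core_epitopes,
                         cluster_epitope_conformations, cluster_mhc,
                         cluster_receptors, distinct_pairs)
from .interface import core_epitope, epitope_site
from .similarity import GDomainRef, PM_TOL, SIMILARITY_RULE, load_gdomain_refs
from .structures import ComplexRecord, ComplexType, classify_antigen, load_complex

__all__ = [
    "FilterConfig",
    "StageCounts",
    "apply_filters",
    "run_ab_ag",
    "run_tcr_pmhc",
    "run_mhc_ligand",
    "run_non_peptidic",
    "load_manifest",
]

FILTER_ORDER = ("mhc_filter", "resolution", "r_free", "missing_cdr", "length")


@dataclass(frozen=True)
class FilterConfig:
    """Filtering and clustering thresholds.

    Defaults are the recommended dataset-generation settings: 3 A maximum
    resolution, no R-free cut, drop complexes with missing CDR backbone,
    50-residue antigen minimum (Ab-Ag), 8-residue core minimum (TCR-pMHC
    and MHC-ligand), 4 A contacts, 70% antigen / 85% core identity, and
    the PMax/PMin rule (1.0, 0.9, 0.6) at 0.5 A distance tolerance.
    """

    max_resolution: float = 3.0
    max_r_free: Optional[float] = None  # disabled by default
    drop_missing_cdr: bool = True
    min_antigen_len: int = 50
    min_core_len: int = 8
    contact_cutoff: float = 4.0
    antigen_identity: float = 70.0
    core_identity: float = 85.0
    pm_tol: float = PM_TOL
    pm_rule: tuple[float, float, float] = SIMILARITY_RULE
    gdomain_qcov: float = 90.0
    gdomain_scov: float = 85.0
    mhc_class_filter: Optional[str] = None
    mhc_organism_filter: Optional[str] = None

    def __post_init__(self):
        if self.max_resolution <= 0 or self.contact_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        for v in (self.antigen_identity, self.core_identity):
            if not 0 < v <= 100:
                raise ValueError("identity thresholds must be in (0, 100]")

    @classmethod
    def from_json(cls, path, **overrides) -> "FilterConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "pm_rule" in data:
            data["pm_rule"] = tuple(data["pm_rule"])
        return cls(**data)


@dataclass
class StageCounts:
    total: int = 0
    peptidic: int = 0
    post_filter: int = 0
    distinct_pairs: int = 0
    attrition: dict = field(default_factory=dict)

    def validate(self):
        if not (self.total >= self.peptidic >= self.post_filter
                >= self.distinct_pairs >= 0):
            raise ValueError(f"inconsistent stage counts: {self}")
        return self


def _receptor_chain_ids(record: ComplexRecord) -> list[str]:
    return [cid for cid, role in record.receptor_chain_roles.items()
            if role in ROLE_PREFIX]


def _has_missing_cdr(record: ComplexRecord) -> bool:
    for cid in _receptor_chain_ids(record):
        cdrs = extract_cdrs(record.numbered_chains[cid])
        if has_missing_cdr_backbone(record, cid, cdrs):
            return True
    return False


def _antigen_length(record: ComplexRecord) -> int:
    return sum(record.structure.chain(cid).n_standard
               for cid in record.antigen_chain_ids)


def _passes_mhc_filters(record: ComplexRecord, config: FilterConfig) -> bool:
    if (config.mhc_class_filter is not None
            and record.mhc_class_annotation != config.mhc_class_filter):
        return False
    if (config.mhc_organism_filter is not None
            and record.organism != config.mhc_organism_filter):
        return False
    return True


def apply_filters(records: Sequence[ComplexRecord], config: FilterConfig,
                  *, length_filter: bool = True, r_free_filter: bool = True
                  ) -> tuple[list[ComplexRecord], dict[str, int], dict]:
    """Apply the quality filters in the fixed evaluation order.

    Returns (kept records, per-filter attrition, cores) where cores maps
    structure id -> CoreEpitope for TCR-pMHC / MHC-ligand records whose
    core had to be computed for the length filter.
    """
    attrition = {name: 0 for name in FILTER_ORDER}
    kept: list[ComplexRecord] = []
    cores: dict[str, object] = {}
    for rec in sorted(records, key=lambda r: r.structure_id):
        if rec.complex_type in (ComplexType.TCR_PMHC, ComplexType.MHC_LIGAND):
            if not _passes_mhc_filters(rec, config):
                attrition["mhc_filter"] += 1
                continue
        res = rec.structure.resolution
        if res is None or res > config.max_resolution:
            attrition["resolution"] += 1
            continue
        if (r_free_filter and config.max_r_free is not None
                and (rec.structure.r_free is None
                     or rec.structure.r_free > config.max_r_free)):
            attrition["r_free"] += 1
            continue
        if (config.drop_missing_cdr and _receptor_chain_ids(rec)
                and _has_missing_cdr(rec)):
            attrition["missing_cdr"] += 1
            continue
        if length_filter and rec.antigen_is_peptidic:
            if rec.complex_type == ComplexType.AB_AG:
                if _antigen_length(rec) < config.min_antigen_len:
                    attrition["length"] += 1
                    continue
            else:
                core = core_epitope(rec, cutoff=config.contact_cutoff)
                cores[rec.structure_id] = core
                if core.length < config.min_core_len:
                    attrition["length"] += 1
                    continue
        kept.append(rec)
    return kept, attrition, cores


def _split_peptidic(records, want_peptidic: bool):
    return [r for r in records
            if (classify_antigen(r) == "peptidic") == want_peptidic]


def _base_row(record: ComplexRecord) -> dict:
    return {
        "structure_id": record.structure_id,
        "complex_type": record.complex_type.value,
        "resolution": record.structure.resolution,
        "r_free": record.structure.r_free,
    }


def _finish_rows(rows: list[dict], key_fields: Sequence[str]) -> tuple[pd.DataFrame, int]:
    resolution_of = {row["structure_id"]: row["resolution"] for row in rows}
    pair_of, reps, n_pairs = distinct_pairs(rows, key_fields, resolution_of)
    rep_ids = set(reps.values())
    for row in rows:
        row["pair_cluster_id"] = pair_of[row["structure_id"]]
        row["is_representative"] = row["structure_id"] in rep_ids
    df = pd.DataFrame(rows).sort_values("structure_id").reset_index(drop=True)
    return df, n_pairs


def run_ab_ag(records: Sequence[ComplexRecord], config: FilterConfig = FilterConfig()
              ) -> tuple[pd.DataFrame, StageCounts, dict]:
    """Ab-Ag branch: peptidic split, quality filters, then antigen /
    receptor-CDR / epitope-conformation clustering and distinct
    (receptor, epitope) pairs."""
    records = [r for r in records if r.complex_type == ComplexType.AB_AG]
    counts = StageCounts(total=len(records))
    peptidic = _split_peptidic(records, True)
    counts.peptidic = len(peptidic)
    kept, attrition, _ = apply_filters(peptidic, config)
    counts.attrition = attrition
    counts.post_filter = len(kept)
    if not kept:
        return pd.DataFrame(), counts.validate(), {
            "antigen_clusters": 0, "receptor_clusters": 0, "distinct_pairs": 0}

    _, ag_labels = cluster_antigens(kept, threshold=config.antigen_identity)
    receptor_part, rec_labels = cluster_receptors(kept)
    sites = {r.structure_id: epitope_site(r, cutoff=config.contact_cutoff)
             for r in kept}

    by_id = {r.structure_id: r for r in kept}
    epitope_labels: dict[str, str] = {}
    for members in receptor_part.clusters():
        _, e_labels = cluster_epitope_conformations(
            [by_id[sid] for sid in members], sites,
            tol=config.pm_tol, rule=config.pm_rule)
        epitope_labels.update(e_labels)

    rows = []
    for rec in kept:
        row = _base_row(rec)
        row.update(
            antigen_cluster=ag_labels[rec.structure_id],
            receptor_cluster=rec_labels[rec.structure_id],
            epitope_cluster=epitope_labels[rec.structure_id],
        )
        rows.append(row)
    df, n_pairs = _finish_rows(rows, ("receptor_cluster", "epitope_cluster"))
    counts.distinct_pairs = n_pairs
    summary = {
        "antigen_clusters": len(set(ag_labels.values())),
        "receptor_clusters": len(set(rec_labels.values())),
        "distinct_pairs": n_pairs,
    }
    return df, counts.validate(), summary


def _run_core_branch(records, config: FilterConfig, refs: Sequence[GDomainRef],
                     complex_type: ComplexType):
    records = [r for r in records if r.complex_type == complex_type]
    counts = StageCounts(total=len(records))
    peptidic = _split_peptidic(records, True)
    counts.peptidic = len(peptidic)
    kept, attrition, cores = apply_filters(peptidic, config)
    counts.attrition = attrition
    counts.post_filter = len(kept)
    return counts, kept, cores


def run_tcr_pmhc(records: Sequence[ComplexRecord],
                 config: FilterConfig = FilterConfig(),
                 refs: Sequence[GDomainRef] = ()
                 ) -> tuple[pd.DataFrame, StageCounts, dict]:
    """TCR-pMHC branch: core-epitope, receptor-CDR and MHC G-domain
    clustering; reports both full (core, TCR, MHC) clusters and
    TCR-epitope groups (core, TCR)."""
    counts, kept, cores = _run_core_branch(records, config, refs,
                                           ComplexType.TCR_PMHC)
    empty_summary = {"core_clusters": 0, "receptor_clusters": 0,
                     "mhc_clusters": 0, "full_clusters": 0,
                     "receptor_epitope_groups": 0}
    if not kept:
        return pd.DataFrame(), counts.validate(), empty_summary

    core_seqs = {sid: core.sequence for sid, core in cores.items()}
    _, core_labels = cluster_core_epitopes(kept, core_seqs,
                                           threshold=config.core_identity)
    _, rec_labels = cluster_receptors(kept)
    _, mhc_labels = cluster_mhc(kept, refs, min_qcov=config.gdomain_qcov,
                                min_scov=config.gdomain_scov)
    rows = []
    for rec in kept:
        row = _base_row(rec)
        row.update(
            core_cluster=core_labels[rec.structure_id],
            receptor_cluster=rec_labels[rec.structure_id],
            mhc_cluster=mhc_labels[rec.structure_id],
            core_sequence=core_seqs[rec.structure_id],
        )
        rows.append(row)
    df, n_full = _finish_rows(
        rows, ("core_cluster", "receptor_cluster", "mhc_cluster"))
    groups = {(row["core_cluster"], row["receptor_cluster"]) for row in rows}
    counts.distinct_pairs = n_full
    summary = {
        "core_clusters": len(set(core_labels.values())),
        "receptor_clusters": len(set(rec_labels.values())),
        "mhc_clusters": len(set(mhc_labels.values())),
        "full_clusters": n_full,
        "receptor_epitope_groups": len(groups),
    }
    return df, counts.validate(), summary


def run_mhc_ligand(records: Sequence[ComplexRecord],
                   config: FilterConfig = FilterConfig(),
                   refs: Sequence[GDomainRef] = ()
                   ) -> tuple[pd.DataFrame, StageCounts, dict]:
    """MHC-ligand branch: core-peptide and MHC G-domain clustering;
    distinct (core, MHC) pairs."""
    counts, kept, cores = _run_core_branch(records, config, refs,
                                           ComplexType.MHC_LIGAND)
    empty_summary = {"core_clusters": 0, "mhc_clusters": 0, "distinct_pairs": 0}
    if not kept:
        return pd.DataFrame(), counts.validate(), empty_summary

    core_seqs = {sid: core.sequence for sid, core in cores.items()}
    _, core_labels = cluster_core_epitopes(kept, core_seqs,
                                           threshold=config.core_identity)
    _, mhc_labels = cluster_mhc(kept, refs, min_qcov=config.gdomain_qcov,
                                min_scov=config.gdomain_scov)
    rows = []
    for rec in kept:
        row = _base_row(rec)
        row.update(
            core_cluster=core_labels[rec.structure_id],
            mhc_cluster=mhc_labels[rec.structure_id],
            core_sequence=core_seqs[rec.structure_id],
        )
        rows.append(row)
    df, n_pairs = _finish_rows(rows, ("core_cluster", "mhc_cluster"))
    counts.distinct_pairs = n_pairs
    summary = {
        "core_clusters": len(set(core_labels.values())),
        "mhc_clusters": len(set(mhc_labels.values())),
        "distinct_pairs": n_pairs,
    }
    return df, counts.validate(), summary


def run_non_peptidic(records: Sequence[ComplexRecord],
                     config: FilterConfig = FilterConfig(),
                     refs: Sequence[GDomainRef] = ()
                     ) -> tuple[pd.DataFrame, dict]:
    """Non-peptidic branch: resolution and missing-CDR filters only, then
    receptor CDR grouping (Ab-Ag, TCR-pMHC) and MHC clustering (TCR-pMHC,
    MHC-ligand); no antigen or epitope clustering."""
    for rec in records:
        if classify_antigen(rec) == "peptidic":
            raise TypeError(
                f"{rec.structure_id} has a peptidic antigen; the "
                "non-peptidic branch accepts only non-peptidic complexes")
    summary: dict = {}
    all_rows: list[dict] = []
    for ctype, key in ((ComplexType.AB_AG, "ab_ag"),
                       (ComplexType.TCR_PMHC, "tcr_pmhc"),
                       (ComplexType.MHC_LIGAND, "mhc_ligand")):
        subset = [r for r in records if r.complex_type == ctype]
        kept, attrition, _ = apply_filters(subset, config,
                                           length_filter=False,
                                           r_free_filter=False)
        branch: dict = {"total": len(subset), "post_filter": len(kept),
                        "attrition": attrition}
        rec_labels: dict[str, str] = {}
        mhc_labels: dict[str, str] = {}
        if kept and ctype in (ComplexType.AB_AG, ComplexType.TCR_PMHC):
            _, rec_labels = cluster_receptors(kept)
            branch["receptor_clusters"] = len(set(rec_labels.values()))
        if kept and ctype in (ComplexType.TCR_PMHC, ComplexType.MHC_LIGAND):
            _, mhc_labels = cluster_mhc(kept, refs,
                                        min_qcov=config.gdomain_qcov,
                                        min_scov=config.gdomain_scov)
            branch["mhc_clusters"] = len(set(mhc_labels.values()))
        for rec in kept:
            row = _base_row(rec)
            row["receptor_cluster"] = rec_labels.get(rec.structure_id, "")
            row["mhc_cluster"] = mhc_labels.get(rec.structure_id, "")
            all_rows.append(row)
        summary[key] = branch
    df = (pd.DataFrame(all_rows).sort_values("structure_id")
          .reset_index(drop=True) if all_rows else pd.DataFrame())
    return df, summary


def run_all(records: Sequence[ComplexRecord],
            config: FilterConfig = FilterConfig(),
            refs: Sequence[GDomainRef] = ()) -> dict:
    """Run all four branches; returns {'tables': ..., 'summary': ...}.

    The summary merges per-branch stage counts with the cluster counts,
    in the same shape the fixture generator's expected-counts record uses.
    """
    ab_df, ab_counts, ab_summary = run_ab_ag(records, config)
    tcr_df, tcr_counts, tcr_summary = run_tcr_pmhc(records, config, refs)
    mhl_df, mhl_counts, mhl_summary = run_mhc_ligand(records, config, refs)
    non_pep = [r for r in records if classify_antigen(r) == "non_peptidic"]
    np_df, np_summary = run_non_peptidic(non_pep, config, refs)

    def merge(counts: StageCounts, summary: dict) -> dict:
        return {"total": counts.total, "peptidic": counts.peptidic,
                "post_filter": counts.post_filter,
                "attrition": dict(counts.attrition), **summary}

    return {
        "tables": {"ab_ag": ab_df, "tcr_pmhc": tcr_df,
                   "mhc_ligand": mhl_df, "non_peptidic": np_df},
        "summary": {"ab_ag": merge(ab_counts, ab_summary),
                    "tcr_pmhc": merge(tcr_counts, tcr_summary),
                    "mhc_ligand": merge(mhl_counts, mhl_summary),
                    "non_peptidic": np_summary},
    }


def write_outputs(out_dir, tables: dict, summary: dict) -> None:
    """Write benchmark TSVs and the counts JSON deterministically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}_benchmark.tsv", sep="\t", index=False,
                  float_format="%.3f")
    (out_dir / "counts.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Manifest I/O

def load_manifest(manifest_path) -> tuple[list[ComplexRecord],
                                          list[GDomainRef], dict]:
    """Load a corpus manifest: complex records, G-domain references and
    the manifest metadata (seed, expected-counts path when present)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    records = [load_complex(base / entry["annotation"])
               for entry in manifest["complexes"]]
    refs: list[GDomainRef] = []
    if manifest.get("g_domain_refs"):
        refs = load_gdomain_refs(base / manifest["g_domain_refs"])
    return records, refs, manifest
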