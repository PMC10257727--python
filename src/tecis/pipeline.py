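"""End-to-end analysis pipeline and report assembly.

Stage order: bias-corrected k-mer deviations -> variability -> de novo motif
assembly -> motif matching -> TE-derived accessible motif detection ->
subfamily enrichment (ES_peak against each ChIP factor, ES_motif per motif,
Fisher/BH, background-corrected robust z) -> TE subfamily accessibility
(cell-count eligibility rule) -> branch statistics and pseudotime segment
profiles -> consensus-coordinate projection -> acquisition-clade dating ->
motif conservation. Every intermediate is serialized into the output
directory and the numeric summary is returned (and written) as report.json.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from tecis import accessibility as acc
from tecis import enrichment as enr
from tecis import evolution as evo
from tecis import motifs as mot
from tecis import trajectory as traj
from tecis.consensus import normalized_coverage_profile, project_feature_counts
from tecis.intervals import GenomicInterval, PeakSet
from tecis.simulate import SyntheticDataset
from tecis.stats import format_percent

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    k: int = 7
    variability_threshold: float = 2.0
    r_min: float = 0.7
    es_threshold: float = 1.5
    n_background: int = 50
    n_bins: int = 25
    n_segments: int = 10
    min_intersections: int = 3
    min_cells_te: int = 100
    scan_p_threshold: float = 1e-4
    kmer_min_support: int = 5
    n_conservation_draws: int = 500
    branch_a: str = "S2_S1"
    branch_b: str = "S0_S1"
    seed: int = 0


def te_annotation(peaks: PeakSet, fragments) -> acc.AnnotationMatrix:
    """Peaks x subfamilies membership: >= 1 bp overlap with any fragment."""
    from intervaltree import IntervalTree

    subfams = sorted({fr.subfamily for fr in fragments})
    sidx = {s: j for j, s in enumerate(subfams)}
    trees: dict[str, IntervalTree] = {}
    for fr in fragments:
        iv = fr.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end,
                                                        fr.subfamily)
    mat = np.zeros((len(peaks), len(subfams)), dtype=np.int8)
    for i, iv in enumerate(peaks.intervals):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for itv in tree.overlap(iv.start, iv.end):
            mat[i, sidx[itv.data]] = 1
    return acc.AnnotationMatrix(sparse.csr_matrix(mat), subfams)


def eligible_subfamilies(X: acc.BinaryAccessibilityMatrix,
                         A: acc.AnnotationMatrix,
                         cell_subset: list[str] | None = None,
                         min_cells: int = 100) -> list[str]:
    """Subfamilies for which more than min_cells of the given cells overlap
    at least one accessible peak of the subfamily."""
    cols = (np.array([c in set(cell_subset) for c in X.cell_ids])
            if cell_subset is not None else np.ones(X.n_cells, dtype=bool))
    V = X.values[:, cols]
    M = A.membership.T @ V  # subfamilies x cells: open subfamily peaks per cell
    n_cells_with = np.asarray((M > 0).sum(axis=1)).ravel()
    return [f for f, n in zip(A.feature_ids, n_cells_with) if n > min_cells]


def run_pipeline(ds: SyntheticDataset, params: PipelineParams | None = None,
                 outdir=None) -> dict:
    params = params or PipelineParams()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _save(df: pd.DataFrame, name: str, **kw):
        if out is not None:
            df.to_csv(out / name, sep="\t", **kw)

    report: dict = {"params": dataclasses.asdict(params),
                    "seed": params.seed}
    X = ds.matrix
    genome_len = ds.genome_len

    # --- deviations over k-mers, variability, de novo motifs
    logger.info("stage: k-mer deviations")
    A_kmer = mot.kmer_annotation(ds.peak_seqs, k=params.k) \
        .filter_min_support(params.kmer_min_support)
    gc = acc.gc_fraction(ds.peak_seqs)
    mean_acc = X.values.mean(axis=1)
    bg = acc.sample_background_peaks(gc, mean_acc,
                                     n_iterations=params.n_background,
                                     n_bins=params.n_bins, seed=params.seed)
    dev_kmer = acc.compute_deviations(X, A_kmer, bg)
    v = acc.feature_variability(dev_kmer)
    var_tbl = pd.DataFrame({"kmer": dev_kmer.feature_ids, "variability": v}) \
        .sort_values("variability", ascending=False)
    _save(var_tbl, "kmer_variability.tsv", index=False)
    report["n_kmers"] = len(dev_kmer.feature_ids)
    report["top_kmer"] = str(var_tbl.iloc[0]["kmer"]) if len(var_tbl) else None
    report["top_kmer_variability"] = (float(var_tbl.iloc[0]["variability"])
                                      if len(var_tbl) else None)

    logger.info("stage: de novo motif assembly")
    pwms = mot.assemble_denovo_motifs(
        dev_kmer, variability_threshold=params.variability_threshold,
        r_min=params.r_min)
    report["n_denovo_motifs"] = len(pwms)
    report["denovo_consensus"] = {p.name: p.consensus() for p in pwms}
    if out is not None and pwms:
        mot.write_meme(pwms, out / "denovo_motifs.meme")

    # --- motif matching and TE-derived motif detection
    hits_by_motif: dict[str, dict] = {}
    te_motif_tables = {}
    if pwms:
        logger.info("stage: motif matching")
        _, all_hits = mot.match_motifs_to_peaks(
            ds.peak_seqs, pwms, peak_ids=ds.peaks.ids,
            p_threshold=params.scan_p_threshold)
        for pwm in pwms:
            hits_by_motif[pwm.name] = {
                pid: [h for h in hs if h.motif == pwm.name]
                for pid, hs in all_hits.items()}
        te_tbl, te_records = enr.detect_te_derived_accessible_motifs(
            ds.peaks, {p: h for p, h in all_hits.items()}, ds.te_fragments)
        _save(te_tbl, "te_derived_motifs.tsv", index=False)
        te_motif_tables["records"] = te_records
        report["n_te_derived_motif_hits"] = int(len(te_records))
    else:
        logger.info("no de novo motifs; downstream TE-motif stages skipped")
        report["n_te_derived_motif_hits"] = 0

    # --- subfamily enrichment
    frag_by_sub = {}
    for fr in ds.te_fragments:
        frag_by_sub.setdefault(fr.subfamily, []).append(fr)

    logger.info("stage: ES_peak per ChIP factor")
    report["es_peak"] = {}
    for factor, chip in ds.chip_peaks.items():
        tbl = enr.enrichment_table_peak(chip, ds.te_fragments, genome_len,
                                        min_intersections=params.min_intersections)
        _save(tbl, f"es_peak_{factor}.tsv", index=False)
        report["es_peak"][factor] = tbl.to_dict("records")

    logger.info("stage: ES_motif per de novo motif")
    report["es_motif"] = {}
    for name, hits in hits_by_motif.items():
        if not any(hits.values()):
            logger.info("motif %s has no peak hits; skipped", name)
            continue
        tbl = enr.enrichment_table_motif(ds.peaks, hits, ds.te_fragments,
                                         genome_len,
                                         min_intersections=params.min_intersections)
        if len(tbl):
            zs = []
            for _, row in tbl.iterrows():
                z = enr.background_corrected_es_z(
                    row["es_motif"], ds.peaks, hits,
                    frag_by_sub[row["subfamily"]], genome_len, bg)
                zs.append(z)
            tbl["robust_z"] = zs
        _save(tbl, f"es_motif_{name}.tsv", index=False)
        report["es_motif"][name] = tbl.to_dict("records")

    # --- TE class composition and per-cell TE fraction
    logger.info("stage: TE composition and per-cell fractions")
    comp_atac = enr.te_class_composition(ds.peaks, ds.te_fragments, mode="atac")
    _save(comp_atac, "te_class_composition_atac.tsv", index=False)
    report["atac_te_percent"] = format_percent(comp_atac.attrs["te_fraction"])
    report["chip_te_percent"] = {}
    for factor, chip in ds.chip_peaks.items():
        comp = enr.te_class_composition(chip, ds.te_fragments, mode="chip")
        _save(comp, f"te_class_composition_chip_{factor}.tsv", index=False)
        report["chip_te_percent"][factor] = format_percent(
            comp.attrs["te_fraction"])

    peak_te_flag = np.array([
        ds.truth["peak_is_te"][pid] for pid in X.peak_ids])
    n_groups = len(set(X.cell_labels.values())) if X.cell_labels else 1
    if n_groups >= 2:
        per_cell, pairwise, kw_p = enr.per_cell_te_fraction(
            X, peak_te_flag, seed=params.seed)
        _save(per_cell, "per_cell_te_fraction.tsv", index=False)
        _save(pairwise, "per_cell_te_fraction_tests.tsv", index=False)
        report["te_fraction_kruskal_p"] = kw_p
        report["te_fraction_group_medians"] = per_cell.groupby("group")[
            "te_fraction"].median().to_dict()
    else:
        logger.info("single cell population: TE-fraction group tests skipped")

    # --- TE accessibility deviations with the cell-count eligibility rule
    logger.info("stage: TE accessibility")
    A_te = te_annotation(ds.peaks, ds.te_fragments)
    neuron_cells = [c for c in X.cell_ids
                    if X.cell_labels and X.cell_labels[c] != "glia"]
    eligible = eligible_subfamilies(X, A_te, neuron_cells,
                                    min_cells=params.min_cells_te)
    keep = [f in eligible for f in A_te.feature_ids]
    A_te_eligible = acc.AnnotationMatrix(
        A_te.membership[:, np.flatnonzero(keep)],
        [f for f, k in zip(A_te.feature_ids, keep) if k])
    report["eligible_te_subfamilies"] = eligible
    dev_te = acc.compute_deviations(X, A_te_eligible, bg)
    dev_frame, z_frame = dev_te.to_frames()
    _save(z_frame, "te_accessibility_z.tsv")

    # --- branch statistics and segment profiles
    logger.info("stage: trajectory statistics")
    n_a = len(ds.pseudotime.cells_on(params.branch_a))
    n_b = len(ds.pseudotime.cells_on(params.branch_b))
    if n_a >= 2 and n_b >= 2 and len(dev_frame):
        branch_cells = set(ds.pseudotime.cells_on(params.branch_a)["cell_id"]) | \
            set(ds.pseudotime.cells_on(params.branch_b)["cell_id"])
        dev_branch = dev_frame[[c for c in dev_frame.columns
                                if c in branch_cells]]
        diff = traj.branch_differential(dev_branch, ds.pseudotime,
                                        params.branch_a, params.branch_b)
        _save(diff, "branch_differential_te.tsv", index=False)
        report["branch_differential_te"] = diff.to_dict("records")
        profiles = {}
        for branch in (params.branch_a, params.branch_b):
            prof = traj.segment_profile(z_frame, ds.pseudotime, branch,
                                        n_segments=params.n_segments)
            _save(prof, f"segment_profile_{branch}.tsv")
            profiles[branch] = prof
        report["segment_profiles"] = {
            b: {f: [None if not np.isfinite(x) else float(x) for x in row]
                for f, row in p.iterrows()}
            for b, p in profiles.items()}
    else:
        logger.info("branches %s/%s not both populated: branch stats skipped",
                    params.branch_a, params.branch_b)

    # --- consensus projection
    logger.info("stage: consensus projection")
    aln_by_sub: dict[str, list] = {}
    frag_sub = {fr.fragment_id: fr.subfamily for fr in ds.te_fragments}
    for aln in ds.alignments:
        aln_by_sub.setdefault(frag_sub[aln.fragment_id], []).append(aln)
    report["projection"] = {}
    for sub, clen in ((s.name, s.consensus_len) for s in ds.config.subfamilies):
        factor = ds.truth.get("factor_of", {}).get(sub)
        if factor is None or factor not in ds.chip_peaks:
            continue
        prof_counts = project_feature_counts(
            ds.chip_peaks[factor], aln_by_sub.get(sub, []), clen, sub)
        prof_norm = normalized_coverage_profile(
            ds.chip_peaks[factor], aln_by_sub.get(sub, []), clen, sub)
        _save(prof_counts.to_frame(), f"projection_chip_{sub}.tsv", index=False)
        _save(prof_norm.to_frame(), f"projection_chip_norm_{sub}.tsv",
              index=False)
        peak_pos = int(np.argmax(prof_counts.counts)) + 1
        report["projection"][sub] = {
            "chip_peak_mode_position": peak_pos,
            "chip_peak_mode_count": float(prof_counts.counts.max()),
        }
        if te_motif_tables:
            site_ivs = [g for h, g, s in te_motif_tables["records"] if s == sub]
            if site_ivs:
                prof_motif = project_feature_counts(
                    PeakSet(site_ivs), aln_by_sub.get(sub, []), clen, sub)
                _save(prof_motif.to_frame(), f"projection_motif_{sub}.tsv",
                      index=False)
                report["projection"][sub]["motif_mode_position"] = \
                    int(np.argmax(prof_motif.counts)) + 1

    # --- acquisition dating
    logger.info("stage: acquisition dating")
    assignments = evo.assign_all(ds.ortholog_table, ds.ladder)
    summary = evo.clade_summary(assignments, ds.ladder)
    _save(summary, "clade_summary.tsv", index=False)
    report["clade_summary"] = summary.to_dict("records")
    planted = [s for s in ds.config.subfamilies if s.planted_motif]
    if len(planted) >= 2:
        a_ids = [f for f in assignments.index if f.startswith(planted[0].name)]
        b_ids = [f for f in assignments.index if f.startswith(planted[1].name)]
        try:
            t, oratio, p = evo.acquisition_independence(
                assignments[a_ids], assignments[b_ids],
                planted[0].acquisition_clade, planted[1].acquisition_clade)
            report["acquisition_independence"] = {
                "table": [t.a, t.b, t.c, t.d], "odds_ratio": oratio, "p": p}
        except ValueError as exc:
            report["acquisition_independence"] = {"error": str(exc)}

    # --- conservation
    if te_motif_tables and te_motif_tables["records"]:
        logger.info("stage: conservation")
        site_ivs = [g for _h, g, _s in te_motif_tables["records"]]
        te_peak_regions = _te_peak_intersection(ds)
        try:
            obs, controls, p = evo.motif_conservation_test(
                ds.conservation, PeakSet(site_ivs), te_peak_regions,
                n_draws=params.n_conservation_draws, seed=params.seed)
            report["conservation"] = {
                "observed_mean": obs,
                "control_mean": float(np.mean(controls)),
                "empirical_p": p,
            }
        except ValueError as exc:
            report["conservation"] = {"error": str(exc)}

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _te_peak_intersection(ds: SyntheticDataset) -> PeakSet:
    """Intersection of ATAC peaks with TE fragments, as intervals."""
    from tecis.intervals import _by_chrom, _union

    peak_u = {c: _union(p) for c, p in _by_chrom(ds.peaks.intervals).items()}
    te_u = {c: _union(p) for c, p in _by_chrom(
        [fr.interval for fr in ds.te_fragments]).items()}
    ivs = []
    for chrom in set(peak_u) & set(te_u):
        ia, ib = peak_u[chrom], te_u[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s, e = max(ia[i][0], ib[j][0]), min(ia[i][1], ib[j][1])
            if s < e:
                ivs.append(GenomicInterval(chrom, s, e))
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    return PeakSet(ivs)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        x = float(obj)
        return x if np.isfinite(x) else None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
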