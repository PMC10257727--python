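"""Synthetic study generator with planted ground truth.

The generator emulates the structure of a single-cell ATAC study of a tissue
with several cell populations and a repeat-rich genome:

* a random genome carrying non-overlapping TE fragments from several
  subfamilies, each fragment a contiguous slice of its subfamily consensus
  (random sub-range and strand, antisense fragments reverse-complemented),
  with the block alignment recorded;
* planted 7-bp motifs written at a fixed consensus position of designated
  subfamilies, so that a known fraction of fragments carries the motif at a
  known genomic location;
* 500-bp accessibility peaks over motif-carrying fragments (population
  specific), over a share of the remaining fragments and over TE-free
  background (open in all populations), plus TE-free population-specific
  peaks, a fraction of which also carry a planted motif;
* a binary peak-by-cell matrix where each cell opens its population's peaks
  with probability p_open and all other peaks with probability p_noise;
* ChIP peaks per planted transcription factor, centered on genomic motif
  instances with jitter plus uniform false positives (optionally with
  synthetic IP/input read intervals);
* pseudotime branch assignments per population;
* an ortholog-presence table placing each fragment's element in all species
  of its subfamily's acquisition clade, with independent flip noise; and
* a conservation track elevated at genomic motif bases.

Everything is drawn from a single seeded generator in a fixed order, so the
same (config, seed) reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tecis.accessibility import BinaryAccessibilityMatrix, write_matrix_tsv
from tecis.consensus import ConsensusAlignment, write_alignments_tsv
from tecis.evolution import CladeLadder, ConservationTrack, OrthologTable
from tecis.intervals import (
    GenomicInterval,
    PeakSet,
    TEFragment,
    write_bed,
    write_repeatmasker,
)
from tecis.motifs import revcomp
from tecis.trajectory import PseudotimeTable

ALPHABET = "ACGT"


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    te_class: str
    consensus_len: int
    n_fragments: int
    planted_motif: str | None = None
    consensus_position: int | None = None  # 1-based
    acquisition_clade: str = "Eutheria"
    motif_carrier_frac: float = 0.8

    def __post_init__(self):
        if self.planted_motif is not None:
            if self.consensus_position is None:
                raise ValueError(f"{self.name}: planted motif needs a position")
            if (self.consensus_position + len(self.planted_motif) - 1
                    > self.consensus_len):
                raise ValueError(
                    f"{self.name}: motif at {self.consensus_position} does not "
                    f"fit in consensus of length {self.consensus_len}")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_cells: int = 200
    n_specific_peaks: int = 40        # TE-free population-specific peaks
    motif_frac: float = 0.0           # fraction of those carrying a planted motif
    planted_motif_of: str | None = None  # subfamily whose motif this population
    # carries; that population also owns the subfamily's motif-carrier TE peaks
    branch_id: str = "S0_S1"
    pt_range: tuple[float, float] = (0.0, 1.0)


def _default_subfamilies() -> list[SubfamilySpec]:
    return [
        SubfamilySpec("MER130", "DNA", 500, 40, "CAGATGG", 216, "Amniota"),
        SubfamilySpec("MamRep434", "DNA", 400, 40, "CTAATTA", 101, "Eutheria"),
        SubfamilySpec("RLTR10", "LTR", 600, 40, None, None, "Rodentia"),
        SubfamilySpec("B2_Mm1", "SINE", 200, 60, None, None, "Muridae"),
    ]


def _default_populations() -> list[PopulationSpec]:
    return [
        PopulationSpec("progenitor", n_cells=200, n_specific_peaks=60,
                       motif_frac=0.8, planted_motif_of="MER130",
                       branch_id="S2_S1", pt_range=(0.0, 1.0)),
        PopulationSpec("neuron", n_cells=200, n_specific_peaks=60,
                       motif_frac=0.8, planted_motif_of="MamRep434",
                       branch_id="S0_S1", pt_range=(0.0, 1.0)),
        PopulationSpec("glia", n_cells=200, n_specific_peaks=40,
                       branch_id="glia", pt_range=(0.0, 1.0)),
    ]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 300_000
    subfamilies: list[SubfamilySpec] = field(default_factory=_default_subfamilies)
    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    peak_width: int = 500
    n_common_peaks: int = 80          # TE-free peaks open in all populations
    te_peak_frac: float = 0.5         # non-carrier fragments receiving a common peak
    p_open: float = 0.85
    p_noise: float = 0.05
    chip_width: int = 200
    chip_jitter: int = 20
    chip_fp_rate: float = 0.2
    emit_reads: bool = False
    n_reads: int = 2000
    read_width: int = 100
    ip_motif_frac: float = 0.5        # IP reads placed at motif sites
    ortholog_flip_prob: float = 0.01
    conservation_background: float = 0.0
    conservation_motif: float = 2.0
    max_placement_attempts: int = 1000

    def __post_init__(self):
        for p in (self.p_open, self.p_noise, self.chip_fp_rate,
                  self.ortholog_flip_prob, self.te_peak_frac,
                  self.ip_motif_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    peaks: PeakSet
    peak_seqs: list[str]
    matrix: BinaryAccessibilityMatrix
    te_fragments: list[TEFragment]
    alignments: list[ConsensusAlignment]
    consensus_seqs: dict[str, str]
    chip_peaks: dict[str, PeakSet]
    ip_reads: dict[str, PeakSet]
    input_reads: dict[str, PeakSet]
    pseudotime: PseudotimeTable
    ortholog_table: OrthologTable
    ladder: CladeLadder
    conservation: ConservationTrack
    truth: dict

    @property
    def genome_len(self) -> int:
        return sum(len(s) for s in self.genome.values())

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        write_bed(self.peaks, out / "peaks.bed")
        write_matrix_tsv(self.matrix, out / "matrix.tsv", out / "cells.tsv")
        write_repeatmasker(self.te_fragments, out / "te.out")
        write_alignments_tsv(self.alignments, out / "te_align.tsv")
        with open(out / "consensus.fa", "w") as fh:
            for name, seq in self.consensus_seqs.items():
                fh.write(f">{name}\n{seq}\n")
        with open(out / "genome.fa", "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n{seq}\n")
        for factor, ps in self.chip_peaks.items():
            write_bed(ps, out / f"chip_{factor}.bed")
        for factor, ps in self.ip_reads.items():
            write_bed(ps, out / f"reads_ip_{factor}.bed")
        for factor, ps in self.input_reads.items():
            write_bed(ps, out / f"reads_input_{factor}.bed")
        self.pseudotime.write_tsv(out / "pseudotime.tsv")
        self.ortholog_table.write_tsv(out / "orthologs.tsv")
        self.ladder.write_yaml(out / "ladder.yaml")
        self.conservation.write_bedgraph(out / "conservation.bedGraph")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=n))


def generate_consensus_library(config: SyntheticConfig,
                               rng: np.random.Generator | None = None
                               ) -> tuple[dict[str, str], dict[str, dict]]:
    """Random consensus sequences with planted motifs written at their stated
    1-based positions. Returns (sequences, motif registry)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    registry: dict[str, dict] = {}
    for sub in config.subfamilies:
        seq = list(_random_seq(rng, sub.consensus_len))
        if sub.planted_motif is not None:
            motif = sub.planted_motif.upper()
            if len(motif) > sub.consensus_len:
                raise ValueError(f"{sub.name}: motif longer than consensus")
            p = sub.consensus_position - 1
            seq[p:p + len(motif)] = motif
            registry[sub.name] = {
                "motif": motif,
                "consensus_position": sub.consensus_position,
            }
        seqs[sub.name] = "".join(seq)
    return seqs, registry


def _place_fragments(config: SyntheticConfig, rng: np.random.Generator,
                     consensus: dict[str, str]):
    """Place non-overlapping fragments; returns fragment metadata."""
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    placements = []
    for sub in config.subfamilies:
        n_carriers = (int(round(sub.motif_carrier_frac * sub.n_fragments))
                      if sub.planted_motif else 0)
        for i in range(sub.n_fragments):
            carrier = i < n_carriers
            L = sub.consensus_len
            if carrier:
                pos = sub.consensus_position
                w = len(sub.planted_motif)
                cb = int(rng.integers(1, pos + 1))
                ce = int(rng.integers(pos + w - 1, L + 1))
            else:
                # slice avoiding the motif (when one is planted) so that
                # carrier status is unambiguous in the truth registry
                if sub.planted_motif:
                    pos = sub.consensus_position
                    w = len(sub.planted_motif)
                    left_room = pos - 1 >= 30
                    if left_room and rng.random() < 0.5:
                        cb = 1
                        ce = int(rng.integers(min(30, pos - 1), pos))
                    else:
                        cb = int(rng.integers(pos + w, max(pos + w + 1, L - 29)))
                        ce = L
                    if ce < cb:
                        cb, ce = ce, cb
                else:
                    cb = int(rng.integers(1, max(2, L // 2)))
                    ce = int(rng.integers(cb + min(30, L - cb) - 1, L + 1))
            frag_len = ce - cb + 1
            strand = "+" if rng.random() < 0.5 else "-"
            placed = False
            for _ in range(config.max_placement_attempts):
                chrom = chrom_names[int(rng.integers(config.n_chroms))]
                start = int(rng.integers(config.peak_width,
                                         config.chrom_len - frag_len
                                         - config.peak_width))
                end = start + frag_len
                if all(end <= s or e <= start for s, e in occupied[chrom]):
                    occupied[chrom].append((start, end))
                    placements.append((sub, i, carrier, chrom, start, end,
                                       cb, ce, strand))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "could not place fragments without overlap; increase "
                    "chrom_len or reduce n_fragments")
    return chrom_names, placements


def generate_ortholog_table(element_ids: list[str], ladder: CladeLadder,
                            planted_clades: dict[str, str], flip_prob: float,
                            seed_or_rng) -> OrthologTable:
    """Presence true for species within each element's planted clade, false
    elsewhere, each call independently flipped with flip_prob."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    species = sorted(ladder.species_universe)
    rows = np.zeros((len(element_ids), len(species)), dtype=bool)
    for i, eid in enumerate(element_ids):
        clade = planted_clades[eid]
        if clade not in ladder.names:
            raise ValueError(f"unknown clade {clade!r} for element {eid}")
        in_clade = ladder.species_sets[ladder.names.index(clade)]
        rows[i] = [sp in in_clade for sp in species]
    if flip_prob > 0:
        flips = rng.random(rows.shape) < flip_prob
        rows ^= flips
    else:
        rng.random(rows.shape)  # keep the stream position stable
    return OrthologTable(pd.DataFrame(rows, index=element_ids, columns=species))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic study. Deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed)

    # 1. consensus library
    consensus, motif_registry = generate_consensus_library(config, rng)

    # 2. genome backbone
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {c: list(_random_seq(rng, config.chrom_len)) for c in chrom_names}

    # 3. fragment placement and sequence write-through
    _, placements = _place_fragments(config, rng, consensus)
    fragments: list[TEFragment] = []
    alignments: list[ConsensusAlignment] = []
    motif_instances: dict[str, list[tuple[str, int, int]]] = {
        sub.name: [] for sub in config.subfamilies}
    carrier_ids: dict[str, list[str]] = {sub.name: [] for sub in config.subfamilies}
    frag_clades: dict[str, str] = {}
    for sub, i, carrier, chrom, start, end, cb, ce, strand in placements:
        frag_id = f"{sub.name}_{i}"
        slice_seq = consensus[sub.name][cb - 1:ce]
        genome_seq = slice_seq if strand == "+" else revcomp(slice_seq)
        genome[chrom][start:end] = genome_seq
        fragments.append(TEFragment(
            interval=GenomicInterval(chrom, start, end, strand),
            subfamily=sub.name, te_class=sub.te_class,
            consensus_span=(cb, ce), fragment_id=frag_id))
        alignments.append(ConsensusAlignment(
            fragment_id=frag_id, genomic_blocks=[(start, end)],
            consensus_blocks=[(cb, ce)], strand=strand, chrom=chrom))
        frag_clades[frag_id] = sub.acquisition_clade
        if carrier:
            pos, w = sub.consensus_position, len(sub.planted_motif)
            if strand == "+":
                gs = start + (pos - cb)
            else:
                gs = start + (ce - (pos + w - 1))
            motif_instances[sub.name].append((chrom, gs, gs + w))
            carrier_ids[sub.name].append(frag_id)

    # 4. peaks
    chrom_sizes = {c: config.chrom_len for c in chrom_names}
    half = config.peak_width // 2
    peak_intervals: list[GenomicInterval] = []
    peak_ids: list[str] = []
    peak_owner: list[str] = []  # "common" or population name
    peak_te: list[bool] = []
    planted_peak_motifs: dict[str, list[tuple[str, int, int]]] = {
        sub.name: [] for sub in config.subfamilies}
    used_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for fr in fragments:
        used_spans[fr.interval.chrom].append((fr.interval.start, fr.interval.end))

    def _add_peak(chrom: str, center: int, owner: str, is_te: bool) -> str:
        s = max(0, center - half)
        e = min(chrom_sizes[chrom], s + config.peak_width)
        pid = f"peak_{len(peak_ids):04d}"
        peak_intervals.append(GenomicInterval(chrom, s, e))
        peak_ids.append(pid)
        peak_owner.append(owner)
        peak_te.append(is_te)
        used_spans[chrom].append((s, e))
        return pid

    def _free_center(width: int) -> tuple[str, int]:
        for _ in range(config.max_placement_attempts):
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            c = int(rng.integers(width, config.chrom_len - width))
            s, e = c - width // 2, c + width // 2
            if all(e <= os_ or oe <= s for os_, oe in used_spans[chrom]):
                return chrom, c
        raise ValueError("could not place TE-free peaks; increase chrom_len")

    def _owner_of(sub_name: str) -> str:
        for p in config.populations:
            if p.planted_motif_of == sub_name:
                return p.name
        return config.populations[0].name

    # 4a. peaks over motif-carrying fragments (owned by the population that
    # carries the subfamily's motif)
    for sub in config.subfamilies:
        for chrom, gs, ge in motif_instances[sub.name]:
            _add_peak(chrom, (gs + ge) // 2, _owner_of(sub.name), True)
    # 4b. common peaks over a share of the remaining fragments
    all_carriers = {fid for ids in carrier_ids.values() for fid in ids}
    for fr in fragments:
        if fr.fragment_id in all_carriers:
            continue
        if rng.random() < config.te_peak_frac:
            iv = fr.interval
            _add_peak(iv.chrom, (iv.start + iv.end) // 2, "common", True)
    # 4c. TE-free common background peaks
    for _ in range(config.n_common_peaks):
        chrom, c = _free_center(config.peak_width)
        _add_peak(chrom, c, "common", False)
    # 4d. TE-free population-specific peaks, some with a planted motif
    for pop in config.populations:
        n_motif = int(round(pop.motif_frac * pop.n_specific_peaks))
        for j in range(pop.n_specific_peaks):
            chrom, c = _free_center(config.peak_width)
            pid = _add_peak(chrom, c, pop.name, False)
            if j < n_motif and pop.planted_motif_of is not None:
                sub = next(s for s in config.subfamilies
                           if s.name == pop.planted_motif_of)
                motif = sub.planted_motif
                gs = c - len(motif) // 2
                genome[chrom][gs:gs + len(motif)] = motif
                planted_peak_motifs[sub.name].append((chrom, gs, gs + len(motif)))

    genome_str = {c: "".join(s) for c, s in genome.items()}
    peaks = PeakSet(list(peak_intervals), ids=list(peak_ids),
                    chrom_sizes=chrom_sizes)
    peak_seqs = [genome_str[iv.chrom][iv.start:iv.end] for iv in peak_intervals]

    # 5. binary matrix
    cell_ids: list[str] = []
    cell_labels: dict[str, str] = {}
    cols = []
    owner_arr = np.array(peak_owner)
    for pop in config.populations:
        own = (owner_arr == "common") | (owner_arr == pop.name)
        probs = np.where(own, config.p_open, config.p_noise)
        draws = rng.random((len(peak_ids), pop.n_cells)) < probs[:, None]
        cols.append(draws)
        for j in range(pop.n_cells):
            cid = f"{pop.name}_{j:03d}"
            cell_ids.append(cid)
            cell_labels[cid] = pop.name
    values = np.concatenate(cols, axis=1).astype(np.int8)
    # guard against (vanishingly rare) all-zero cells
    empty = values.sum(axis=0) == 0
    if empty.any():
        values[0, empty] = 1
    matrix = BinaryAccessibilityMatrix(values, list(peak_ids), cell_ids,
                                       cell_labels)

    # 6. ChIP peaks per planted factor, plus optional reads
    chip_peaks: dict[str, PeakSet] = {}
    ip_reads: dict[str, PeakSet] = {}
    input_reads: dict[str, PeakSet] = {}
    factor_of = {"MER130": "Neurod2", "MamRep434": "Lhx2"}
    for sub in config.subfamilies:
        if sub.planted_motif is None:
            continue
        factor = factor_of.get(sub.name, f"TF_{sub.name}")
        sites = motif_instances[sub.name] + planted_peak_motifs[sub.name]
        ivs = []
        cw = config.chip_width
        for chrom, gs, ge in sites:
            center = (gs + ge) // 2 + int(rng.integers(-config.chip_jitter,
                                                       config.chip_jitter + 1))
            s = max(0, center - cw // 2)
            ivs.append(GenomicInterval(chrom, s, min(chrom_sizes[chrom],
                                                     s + cw)))
        n_fp = int(round(config.chip_fp_rate * len(ivs)))
        for _ in range(n_fp):
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            s = int(rng.integers(0, config.chrom_len - cw))
            ivs.append(GenomicInterval(chrom, s, s + cw))
        chip_peaks[factor] = PeakSet(ivs, chrom_sizes=chrom_sizes)

        if config.emit_reads:
            rw = config.read_width
            ip, inp = [], []
            for _ in range(config.n_reads):
                if rng.random() < config.ip_motif_frac and sites:
                    chrom, gs, ge = sites[int(rng.integers(len(sites)))]
                    c = (gs + ge) // 2 + int(rng.integers(-rw // 4, rw // 4 + 1))
                else:
                    chrom = chrom_names[int(rng.integers(config.n_chroms))]
                    c = int(rng.integers(rw, config.chrom_len - rw))
                s = max(0, c - rw // 2)
                ip.append(GenomicInterval(chrom, s, s + rw))
            for _ in range(config.n_reads):
                chrom = chrom_names[int(rng.integers(config.n_chroms))]
                c = int(rng.integers(rw, config.chrom_len - rw))
                inp.append(GenomicInterval(chrom, c - rw // 2, c + rw // 2))
            ip_reads[factor] = PeakSet(ip, chrom_sizes=chrom_sizes)
            input_reads[factor] = PeakSet(inp, chrom_sizes=chrom_sizes)

    # 7. pseudotime
    pt_rows = []
    for pop in config.populations:
        lo, hi = pop.pt_range
        ts = lo + (hi - lo) * rng.random(pop.n_cells)
        sign = -1.0 if "S2" in pop.branch_id else 1.0
        for j, t in enumerate(ts):
            pt_rows.append((f"{pop.name}_{j:03d}", pop.branch_id, float(t),
                            float(sign * t)))
    pseudotime = PseudotimeTable(pd.DataFrame(
        pt_rows, columns=["cell_id", "branch_id", "pseudotime",
                          "signed_position"]))

    # 8. ortholog table over fragments
    ladder = CladeLadder.default()
    element_ids = [fr.fragment_id for fr in fragments]
    ortholog_table = generate_ortholog_table(
        element_ids, ladder, frag_clades, config.ortholog_flip_prob, rng)

    # 9. conservation track: background everywhere, elevated at motif bases
    all_sites: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for sub in config.subfamilies:
        for chrom, gs, ge in (motif_instances[sub.name]
                              + planted_peak_motifs[sub.name]):
            all_sites[chrom].append((gs, ge))
    rows = []
    for chrom in chrom_names:
        pos = 0
        for gs, ge in sorted(all_sites[chrom]):
            if gs > pos:
                rows.append((chrom, pos, gs, config.conservation_background))
            rows.append((chrom, gs, ge, config.conservation_motif))
            pos = ge
        if pos < config.chrom_len:
            rows.append((chrom, pos, config.chrom_len,
                         config.conservation_background))
    conservation = ConservationTrack.from_intervals(rows)

    truth = {
        "motif_registry": motif_registry,
        "motif_instances": motif_instances,
        "planted_peak_motifs": planted_peak_motifs,
        "carrier_fragments": carrier_ids,
        "fragment_clades": frag_clades,
        "factor_of": {s: factor_of.get(s, f"TF_{s}") for s in motif_registry},
        "peak_owner": dict(zip(peak_ids, peak_owner)),
        "peak_is_te": dict(zip(peak_ids, map(bool, peak_te))),
        "owner_population": {s: _owner_of(s) for s in motif_registry},
        "populations": {p.name: p.n_cells for p in config.populations},
    }
    return SyntheticDataset(
        config=config, genome=genome_str, peaks=peaks, peak_seqs=peak_seqs,
        matrix=matrix, te_fragments=fragments, alignments=alignments,
        consensus_seqs=consensus, chip_peaks=chip_peaks, ip_reads=ip_reads,
        input_reads=input_reads, pseudotime=pseudotime,
        ortholog_table=ortholog_table, ladder=ladder,
        conservation=conservation, truth=truth)


def null_config(seed: int = 0, n_cells: int = 500,
                n_peaks: int = 150) -> SyntheticConfig:
    """A configuration with no planted structure: one population, no motifs,
    no population-specific peaks — used for null calibration."""
    return SyntheticConfig(
        seed=seed,
        subfamilies=[
            SubfamilySpec("RLTR10", "LTR", 600, 20, None, None, "Rodentia"),
            SubfamilySpec("B2_Mm1", "SINE", 200, 20, None, None, "Muridae"),
        ],
        populations=[PopulationSpec("bulk", n_cells=n_cells,
                                    n_specific_peaks=0)],
        n_common_peaks=n_peaks,
    )
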