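"""Evolutionary dating of cis-elements and motif-site conservation testing.

An element's acquisition clade is the most inclusive ancestral clade in which
an orthologous sequence is still detectable: given a ladder of nested clades
ordered outward from the focal species (mouse), the element is assigned to
the outermost clade containing at least one species where its ortholog is
present. Elements with no ortholog anywhere are focal-lineage-specific.

Motif-site conservation is tested against shuffled controls: the observed
mean per-bp conservation score over all motif-site bases is compared with
control draws that place one same-width window per motif site uniformly into
the TE-overlapping peak space outside the motif sites, without overlap
within a draw; the empirical p-value is add-one corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from tecis.enrichment import ContingencyTable, contingency_fisher
from tecis.intervals import GenomicInterval, PeakSet, _by_chrom, _union

FOCAL_LABEL = "focal-lineage-specific"

# The 17-species ladder grouped into nested clades ordered outward from
# mouse. Divergence-time labels are display metadata only.
DEFAULT_LADDER_SPEC: list[tuple[str, list[str], str]] = [
    ("Muridae", ["rat"], "20-29 Mya"),
    ("Rodentia", ["guinea_pig"], "69-77 Mya"),
    ("Euarchontoglires", ["rabbit", "human"], "82-95 Mya"),
    ("Eutheria", ["cow", "dog", "horse", "tenrec", "elephant"], "95-113 Mya"),
    ("Theria", ["opossum"], "143-178 Mya"),
    ("Mammalia", ["platypus"], "160-191 Mya"),
    ("Amniota", ["chicken", "turkey", "lizard"], "297-326 Mya"),
    ("Tetrapoda", ["xenopus"], "330-368 Mya"),
    ("Vertebrata", ["zebrafish", "medaka"], "419-458 Mya"),
]


@dataclass
class CladeLadder:
    """Ordered clades from the focal species outward with cumulative species
    sets (each clade's set contains every inner clade's species)."""

    names: list[str]
    species_sets: list[frozenset[str]]  # cumulative, strictly nested outward
    divergence: list[str]

    def __post_init__(self):
        prev: frozenset[str] = frozenset()
        for name, ss in zip(self.names, self.species_sets):
            if not ss > prev:
                raise ValueError(f"clade {name} does not strictly extend the "
                                 "previous clade's species set")
            prev = ss

    @property
    def species_universe(self) -> frozenset[str]:
        return self.species_sets[-1]

    def new_species_of(self, clade: str) -> frozenset[str]:
        """Species first appearing at the given clade level."""
        i = self.names.index(clade)
        inner = self.species_sets[i - 1] if i else frozenset()
        return self.species_sets[i] - inner

    @classmethod
    def from_spec(cls, spec: Sequence[tuple[str, Sequence[str], str]]
                  ) -> "CladeLadder":
        names, sets, div = [], [], []
        acc: set[str] = set()
        for name, species, mya in spec:
            acc |= set(species)
            names.append(name)
            sets.append(frozenset(acc))
            div.append(mya)
        return cls(names, sets, div)

    @classmethod
    def default(cls) -> "CladeLadder":
        return cls.from_spec(DEFAULT_LADDER_SPEC)

    @classmethod
    def read_yaml(cls, path) -> "CladeLadder":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_spec([(d["clade"], d["species"], d.get("divergence", ""))
                              for d in data])

    def write_yaml(self, path) -> None:
        prev: frozenset[str] = frozenset()
        data = []
        for name, ss, mya in zip(self.names, self.species_sets, self.divergence):
            data.append({"clade": name, "species": sorted(ss - prev),
                         "divergence": mya})
            prev = ss
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class OrthologTable:
    """Element x species boolean presence (the focal species is implicit)."""

    presence: pd.DataFrame  # index element_id, bool columns per species

    def __post_init__(self):
        if self.presence.index.duplicated().any():
            raise ValueError("duplicate element ids")
        self.presence = self.presence.astype(bool)

    def species_of(self, element_id: str) -> set[str]:
        row = self.presence.loc[element_id]
        return set(row.index[row])

    @classmethod
    def read_tsv(cls, path) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.presence.rename_axis("element_id").to_csv(path, sep="\t")


def assign_acquisition_clade(presence: Iterable[str], ladder: CladeLadder) -> str:
    """Outermost ladder clade containing >= 1 present species; the focal
    lineage label when no ortholog is present anywhere."""
    present = set(presence)
    unknown = present - ladder.species_universe
    if unknown:
        raise ValueError(f"species not in ladder: {sorted(unknown)}")
    for name in reversed(ladder.names):
        if present & ladder.new_species_of(name):
            return name
    return FOCAL_LABEL


def assign_all(table: OrthologTable, ladder: CladeLadder) -> pd.Series:
    """Acquisition clade per element."""
    out = {}
    for eid in table.presence.index:
        out[eid] = assign_acquisition_clade(table.species_of(eid), ladder)
    return pd.Series(out, name="clade")


def clade_summary(assignments: pd.Series, ladder: CladeLadder,
                  total_n: int | None = None) -> pd.DataFrame:
    """(clade, count, percent) over the ladder order plus the focal label."""
    total = total_n if total_n is not None else len(assignments)
    rows = []
    order = [FOCAL_LABEL] + list(ladder.names)
    for clade in order:
        count = int((assignments == clade).sum())
        rows.append((clade, count, 100.0 * count / total if total else 0.0))
    return pd.DataFrame(rows, columns=["clade", "count", "percent"])


def acquisition_independence(assignments_a: pd.Series, assignments_b: pd.Series,
                             clade_1: str, clade_2: str
                             ) -> tuple[ContingencyTable, float, float]:
    """Fisher's exact test of clade composition between two element sets,
    restricted to two clades. Returns (table, odds ratio, p)."""
    a1 = int((assignments_a == clade_1).sum())
    a2 = int((assignments_a == clade_2).sum())
    b1 = int((assignments_b == clade_1).sum())
    b2 = int((assignments_b == clade_2).sum())
    if a1 + a2 == 0 or b1 + b2 == 0:
        raise ValueError("both element sets need >= 1 element in the two clades")
    t = ContingencyTable(a1, a2, b1, b2)
    oratio, p = contingency_fisher(t)
    return t, oratio, p


# ---------------------------------------------------------------------------
# Conservation track and shuffle test

@dataclass
class ConservationTrack:
    """Per-base scores with bedGraph semantics (non-overlapping intervals)."""

    frames: dict[str, pd.DataFrame]  # chrom -> (start, end, score) sorted

    @classmethod
    def from_intervals(cls, rows: Iterable[tuple[str, int, int, float]]
                       ) -> "ConservationTrack":
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        frames = {}
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("start").reset_index(drop=True)
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            frames[chrom] = sub
        return cls(frames)

    @classmethod
    def read_bedgraph(cls, path) -> "ConservationTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split("\t")
                rows.append((chrom, int(s), int(e), float(v)))
        return cls.from_intervals(rows)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.frames):
                for _, r in self.frames[chrom].iterrows():
                    fh.write(f"{chrom}\t{int(r.start)}\t{int(r.end)}\t{r.score:g}\n")

    def mean_score(self, intervals: Iterable[GenomicInterval],
                   default: float = 0.0) -> float:
        """Mean per-bp score over all bases of the intervals; bases not
        covered by the track take the default score."""
        total = 0.0
        n = 0
        for iv in intervals:
            n += len(iv)
            sub = self.frames.get(iv.chrom)
            if sub is None:
                total += default * len(iv)
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            scores = sub["score"].to_numpy()
            lo = np.searchsorted(ends, iv.start, side="right")
            hi = np.searchsorted(starts, iv.end, side="left")
            covered = 0
            for j in range(lo, hi):
                s = max(iv.start, starts[j])
                e = min(iv.end, ends[j])
                if s < e:
                    total += scores[j] * (e - s)
                    covered += e - s
            total += default * (len(iv) - covered)
        if n == 0:
            raise ValueError("no bases to score")
        return total / n


def _subtract(space: dict[str, list[tuple[int, int]]],
              remove: dict[str, list[tuple[int, int]]]
              ) -> list[tuple[str, int, int]]:
    """Set-difference of per-chrom interval unions, as (chrom, start, end)."""
    out = []
    for chrom, ivs in space.items():
        cut = _union(remove.get(chrom, []))
        for s, e in _union(ivs):
            pos = s
            for rs, re in cut:
                if re <= pos or rs >= e:
                    continue
                if rs > pos:
                    out.append((chrom, pos, rs))
                pos = max(pos, re)
                if pos >= e:
                    break
            if pos < e:
                out.append((chrom, pos, e))
    return out


def motif_conservation_test(track: ConservationTrack, motif_sites: PeakSet,
                            te_peak_regions: PeakSet, window: int = 7,
                            n_draws: int = 500, seed: int = 0,
                            max_attempts: int = 100
                            ) -> tuple[float, np.ndarray, float]:
    """Shuffle test of motif-site conservation.

    observed = mean per-bp score over all motif-site bases. Each of n_draws
    controls samples one window-bp interval per motif site uniformly from the
    TE-overlapping peak space minus the motif sites, rejecting overlaps
    within the draw, and records the mean score. Returns
    (observed_mean, control_means, empirical_p) with
    p = (1 + #{controls >= observed}) / (n_draws + 1).
    """
    sites = list(motif_sites)
    if not sites:
        raise ValueError("no motif sites")
    observed = track.mean_score(sites)

    space = _subtract(_by_chrom(te_peak_regions.intervals),
                      _by_chrom(sites))
    space = [(c, s, e) for c, s, e in space if e - s >= window]
    if not space:
        raise ValueError(
            f"insufficient control space: need >= {window * len(sites)} bp of "
            "TE-peak regions outside the motif sites")
    slots = np.array([e - s - window + 1 for _, s, e in space])
    total_slots = int(slots.sum())
    if total_slots < len(sites):
        raise ValueError(
            f"insufficient control space for {len(sites)} non-overlapping "
            f"windows: need >= {window * len(sites)} bp, have {slots.sum()}")
    cum = np.cumsum(slots)
    rng = np.random.default_rng(seed)

    control_means = np.empty(n_draws)
    for d in range(n_draws):
        chosen: list[GenomicInterval] = []
        occupied: dict[str, list[tuple[int, int]]] = {}
        for _ in range(len(sites)):
            for _attempt in range(max_attempts):
                r = int(rng.integers(total_slots))
                k = int(np.searchsorted(cum, r, side="right"))
                chrom, s0, _e0 = space[k]
                off = r - (cum[k - 1] if k else 0)
                s = s0 + off
                e = s + window
                if any(s < oe and os_ < e for os_, oe in occupied.get(chrom, [])):
                    continue
                occupied.setdefault(chrom, []).append((s, e))
                chosen.append(GenomicInterval(chrom, s, e))
                break
            else:
                raise ValueError(
                    "could not place non-overlapping control windows; need "
                    f"more than {window * len(sites)} bp of control space")
        control_means[d] = track.mean_score(chosen)

    p = (1 + int((control_means >= observed).sum())) / (n_draws + 1)
    return observed, control_means, p
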