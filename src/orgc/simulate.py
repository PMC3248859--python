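"""Synthetic planted genomes, shredded contig graphs, and desk-scale experiments.

The generator emulates the mixture seen in total-DNA shotgun sequencing of
a plant leaf:

* a chloroplast-like circular genome with the quadripartite LSC + IRa +
  SSC + IRb layout (IRb the reverse complement of IRa), sequenced at high
  fold-coverage (default 87x single-copy, so ~174x in the collapsed IR);
* a mitochondrion-like circular genome carrying dispersed two-or-more-copy
  repeats, at intermediate coverage (default 43x);
* a low-coverage nuclear background of linear fragments (default 9x).

Genomes are cut into contigs at random breakpoints (with forced
breakpoints at every repeat boundary); identical repeat copies collapse
into a single contig whose depth is copies x base depth, exactly as an
overlap assembler collapses them. Adjacent contigs are joined by
well-supported edges, and a configurable number of spurious low-support
cross-genome links is injected. The planted truth (sequences, labels,
multiplicities, flank pairings) is retained as the oracle for tests.

Default sizes are scaled down from real plastid/mitochondrial genomes
(16 kb cp, 40 kb mt, 200 kb nuclear) — every code path of the assembly
procedure is exercised at a fraction of the cost, and all sizes are
configurable.

``subsample_experiment`` reproduces, at desk scale, the
minimal-sequencing-data question: how much total shotgun data must be
sampled before each organellar genome is fully covered. Reads are drawn
from genomes in proportion to copy-depth-weighted genome mass, and
coverage is evaluated on the planted genome positions; samples at
successive data points are nested, so coverage is monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Label
from .graphio import (
    ContigEdge,
    ContigGraph,
    ContigNode,
    End,
    EndRef,
    LinkRecord,
    LinkTable,
)
from .seqs import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeKind",
    "GenomeSpec",
    "RepeatSpec",
    "SyntheticTruth",
    "make_cp_genome",
    "make_mt_genome",
    "make_nuclear_background",
    "shred_to_graph",
    "simulate_link_table",
    "subsample_experiment",
    "simulate_dataset",
    "SimulatedDataset",
]

GenomeKind = Label  # CP / MT / NUCLEAR

_BASES = np.array(list("ACGT"))

DEFAULT_DEPTHS = {"cp": 87.0, "mt": 43.0, "nuclear": 9.0}


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


@dataclass(frozen=True)
class RepeatSpec:
    repeat_len: int
    n_copies: int = 2
    inverted: bool = False

    def __post_init__(self) -> None:
        if self.repeat_len < 1:
            raise ValueError("repeat_len must be >= 1")
        if self.n_copies < 2:
            raise ValueError("a repeat needs >= 2 copies")


@dataclass
class GenomeSpec:
    """Parameters of one planted genome."""

    kind: Label
    copy_depth: float
    gc: float = 0.40
    # CP layout
    lsc_len: int = 8000
    ssc_len: int = 2000
    ir_len: int = 3000
    # MT layout
    total_len: int = 40000
    repeat_specs: tuple[RepeatSpec, ...] = ()
    # NUCLEAR layout
    n_fragments: int = 20

    def __post_init__(self) -> None:
        if self.copy_depth <= 0:
            raise ValueError("copy_depth must be > 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.kind is Label.CP and min(self.lsc_len, self.ssc_len, self.ir_len) < 1:
            raise ValueError("cp region lengths must be >= 1")
        if self.kind in (Label.MT, Label.NUCLEAR) and self.total_len < 1:
            raise ValueError("total_len must be >= 1")


@dataclass(frozen=True)
class RepeatRegion:
    """One placed copy of a repeat on a planted genome (0-based, half-open)."""

    repeat_id: str
    start: int
    end: int
    reversed_copy: bool  # True when this copy is the reverse complement


@dataclass
class SyntheticTruth:
    """Planted ground truth used as the oracle by tests and experiments."""

    genomes: dict[str, str] = field(default_factory=dict)
    kinds: dict[str, Label] = field(default_factory=dict)
    depths: dict[str, float] = field(default_factory=dict)
    circular: dict[str, bool] = field(default_factory=dict)
    repeat_regions: dict[str, list[RepeatRegion]] = field(default_factory=dict)
    cp_layout: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # filled by shred_to_graph:
    contig_labels: dict[str, str] = field(default_factory=dict)
    multiplicities: dict[str, int] = field(default_factory=dict)
    breakpoints: dict[str, list[int]] = field(default_factory=dict)
    tilings: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    link_truth: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def organelle_names(self) -> list[str]:
        return [n for n, k in self.kinds.items() if k in (Label.CP, Label.MT)]

    def acceptable_canonical_forms(self, name: str) -> set[str]:
        """Canonical forms a correct assembly of ``name`` may produce.

        For a quadripartite plastid this is a two-element set: the planted
        sequence and its small-single-copy flip isomer. The two isomers
        interconvert through recombination across the inverted repeat and
        are the same molecule population; a contig graph cannot distinguish
        them.
        """
        from .build import canonical_form

        forms = {canonical_form(self.genomes[name])}
        layout = self.cp_layout.get(name)
        if layout is not None:
            lsc, ssc, ir = layout
            g = self.genomes[name]
            l, ira = g[:lsc], g[lsc : lsc + ir]
            s, irb = g[lsc + ir : lsc + ir + ssc], g[lsc + ir + ssc :]
            forms.add(canonical_form(l + ira + revcomp(s) + irb))
        return forms


# ---------------------------------------------------------------------------
# Genome generators
# ---------------------------------------------------------------------------


def make_cp_genome(
    spec: GenomeSpec,
    seed: int,
    name: str = "cp",
    truth: SyntheticTruth | None = None,
) -> tuple[str, SyntheticTruth]:
    """Plant a quadripartite plastid-like circular genome."""
    if spec.kind is not Label.CP:
        raise ValueError("make_cp_genome needs a CP spec")
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    lsc = _random_seq(rng, spec.lsc_len, spec.gc)
    ira = _random_seq(rng, spec.ir_len, spec.gc)
    ssc = _random_seq(rng, spec.ssc_len, spec.gc)
    genome = lsc + ira + ssc + revcomp(ira)
    truth.genomes[name] = genome
    truth.kinds[name] = Label.CP
    truth.depths[name] = spec.copy_depth
    truth.circular[name] = True
    truth.cp_layout[name] = (spec.lsc_len, spec.ssc_len, spec.ir_len)
    a0 = spec.lsc_len
    b0 = spec.lsc_len + spec.ir_len + spec.ssc_len
    truth.repeat_regions[name] = [
        RepeatRegion("IR", a0, a0 + spec.ir_len, reversed_copy=False),
        RepeatRegion("IR", b0, b0 + spec.ir_len, reversed_copy=True),
    ]
    return genome, truth


def make_mt_genome(
    spec: GenomeSpec,
    seed: int,
    name: str = "mt",
    truth: SyntheticTruth | None = None,
    min_unique: int = 800,
) -> tuple[str, SyntheticTruth]:
    """Plant a mitochondrion-like circular genome with dispersed repeats.

    Repeat copies are byte-identical (reverse-complemented when the spec's
    inverted flag is set, for copies after the first) and are separated by
    unique segments of at least ``min_unique`` bases so that every copy has
    distinct flanking sequence.
    """
    if spec.kind is not Label.MT:
        raise ValueError("make_mt_genome needs an MT spec")
    if not spec.repeat_specs:
        raise ValueError("an mt spec needs at least one repeat")
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    slots: list[tuple[str, int, bool]] = []  # (repeat id, copy index, reversed)
    rep_seqs: dict[str, str] = {}
    for ri, rep in enumerate(spec.repeat_specs):
        rep_id = f"R{ri + 1}"
        rep_seqs[rep_id] = _random_seq(rng, rep.repeat_len, spec.gc)
        for copy in range(rep.n_copies):
            slots.append((rep_id, copy, rep.inverted and copy > 0))
    total_rep = sum(
        r.repeat_len * r.n_copies for r in spec.repeat_specs
    )
    n_slots = len(slots)
    unique_total = spec.total_len - total_rep
    if unique_total < n_slots * min_unique:
        raise ValueError(
            f"repeats do not fit: {unique_total} unique bases cannot hold "
            f"{n_slots} separators of >= {min_unique} bases"
        )
    order = rng.permutation(n_slots)
    extra = rng.multinomial(unique_total - n_slots * min_unique, [1 / n_slots] * n_slots)
    parts: list[str] = []
    regions: list[RepeatRegion] = []
    pos = 0
    for j in range(n_slots):
        useg = _random_seq(rng, min_unique + int(extra[j]), spec.gc)
        parts.append(useg)
        pos += len(useg)
        rep_id, _, rev = slots[order[j]]
        seq = rep_seqs[rep_id]
        if rev:
            seq = revcomp(seq)
        parts.append(seq)
        regions.append(RepeatRegion(rep_id, pos, pos + len(seq), reversed_copy=rev))
        pos += len(seq)
    genome = "".join(parts)
    assert len(genome) == spec.total_len
    truth.genomes[name] = genome
    truth.kinds[name] = Label.MT
    truth.depths[name] = spec.copy_depth
    truth.circular[name] = True
    truth.repeat_regions[name] = regions
    return genome, truth


def make_nuclear_background(
    spec: GenomeSpec,
    seed: int,
    name_prefix: str = "nuc",
    truth: SyntheticTruth | None = None,
) -> SyntheticTruth:
    """Plant low-depth linear nuclear fragments (no repeats)."""
    if spec.kind is not Label.NUCLEAR:
        raise ValueError("make_nuclear_background needs a NUCLEAR spec")
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    frag_len = spec.total_len // spec.n_fragments
    for i in range(spec.n_fragments):
        name = f"{name_prefix}{i:02d}"
        truth.genomes[name] = _random_seq(rng, frag_len, spec.gc)
        truth.kinds[name] = Label.NUCLEAR
        truth.depths[name] = spec.copy_depth
        truth.circular[name] = False
        truth.repeat_regions[name] = []
    return truth


# ---------------------------------------------------------------------------
# Shredding into a contig graph
# ---------------------------------------------------------------------------


def _unique_breakpoints(
    rng: np.random.Generator,
    start: int,
    end: int,
    mean_contig_len: float,
    min_len: int,
    force_midpoint: bool,
) -> list[int]:
    """Random breakpoints inside [start, end) with exponential spacing."""
    points: list[int] = []
    pos = start
    while True:
        pos += max(min_len, int(round(rng.exponential(mean_contig_len))))
        if pos >= end - min_len:
            break
        points.append(pos)
    if force_midpoint and not points and end - start >= 2 * min_len:
        points.append((start + end) // 2)
    return points


def shred_to_graph(
    truth: SyntheticTruth,
    mean_contig_len: int = 1000,
    depth_noise_sd: float = 3.0,
    cross_links: int = 6,
    seed: int = 0,
    min_contig_len: int = 150,
) -> tuple[ContigGraph, SyntheticTruth]:
    """Cut planted genomes into a depth-annotated contig graph.

    Breakpoints are forced at every repeat boundary; identical repeat
    copies collapse into one contig at copies x base depth. Consecutive
    contigs are joined by edges whose spanning-read support scales with
    depth; ``cross_links`` spurious support-1 edges are injected between
    contigs of different genomes. Unique intervals between two repeat
    copies are guaranteed at least two contigs so that every repeat copy
    has a distinct flanking contig on each side.
    """
    if mean_contig_len < 200:
        raise ValueError("mean_contig_len must be >= 200")
    rng = np.random.default_rng(seed)
    graph = ContigGraph()
    for name in truth.genomes:
        genome = truth.genomes[name]
        L = len(genome)
        if mean_contig_len >= L:
            raise ValueError(f"mean_contig_len {mean_contig_len} >= genome {name} length {L}")
        regions = sorted(truth.repeat_regions.get(name, []), key=lambda r: r.start)
        depth = truth.depths[name]
        copies: dict[str, int] = {}
        for reg in regions:
            copies[reg.repeat_id] = copies.get(reg.repeat_id, 0) + 1

        # repeat contigs: one node per repeat id, forward-orientation sequence
        rep_contig: dict[str, str] = {}
        for reg in regions:
            if reg.repeat_id in rep_contig:
                continue
            cid = f"{name}_{reg.repeat_id}"
            seq = genome[reg.start : reg.end]
            if reg.reversed_copy:
                seq = revcomp(seq)
            m = copies[reg.repeat_id]
            d = max(0.5, m * depth + rng.normal(0.0, depth_noise_sd))
            graph.add_node(ContigNode(contig_id=cid, length=len(seq), read_depth=d, sequence=seq))
            rep_contig[reg.repeat_id] = cid
            truth.contig_labels[cid] = name
            truth.multiplicities[cid] = m

        # unique intervals between repeat regions (circular) or fragment ends
        bnds: list[int] = []
        tiling: list[tuple[str, str]] = []
        intervals: list[tuple[int, int]] = []
        if regions:
            for i, reg in enumerate(regions):
                if i + 1 < len(regions):
                    intervals.append((reg.end, regions[i + 1].start))
                else:
                    # from the last repeat, through the origin, to the first
                    intervals.append((reg.end, L + regions[0].start))
        else:
            intervals.append((0, L))

        uniq_idx = 0
        interval_contigs: list[list[tuple[str, str]]] = []
        for a, b in intervals:
            pts = _unique_breakpoints(
                rng, a, b, mean_contig_len, min_contig_len, force_midpoint=bool(regions)
            )
            cuts = [a, *pts, b]
            row: list[tuple[str, str]] = []
            for s, e in zip(cuts[:-1], cuts[1:]):
                cid = f"{name}_c{uniq_idx:03d}"
                uniq_idx += 1
                if e <= L:
                    seq = genome[s:e]
                elif s >= L:
                    seq = genome[s - L : e - L]
                else:
                    seq = genome[s:] + genome[: e - L]
                d = max(0.5, depth + rng.normal(0.0, depth_noise_sd))
                graph.add_node(
                    ContigNode(contig_id=cid, length=len(seq), read_depth=d, sequence=seq)
                )
                truth.contig_labels[cid] = name
                truth.multiplicities[cid] = 1
                row.append((cid, "+"))
                bnds.append(s % L)
            interval_contigs.append(row)

        # stitch the tiling: repeat copy i is followed by interval i
        if regions:
            for i, reg in enumerate(regions):
                tiling.append((rep_contig[reg.repeat_id], "-" if reg.reversed_copy else "+"))
                tiling.extend(interval_contigs[i])
                bnds.append(reg.start)
            # link truth per repeat occurrence: (preceding contig, following contig)
            for i, reg in enumerate(regions):
                prev_row = interval_contigs[(i - 1) % len(regions)]
                next_row = interval_contigs[i]
                key = rep_contig[reg.repeat_id]
                truth.link_truth.setdefault(key, []).append(
                    (prev_row[-1][0], next_row[0][0])
                )
        else:
            tiling = interval_contigs[0]
        truth.tilings[name] = tiling
        truth.breakpoints[name] = sorted(set(bnds))

        # adjacency edges along the tiling
        n_steps = len(tiling)
        last = n_steps if truth.circular[name] else n_steps - 1
        for i in range(last):
            cid, o = tiling[i]
            nid, no = tiling[(i + 1) % n_steps]
            a = EndRef(cid, End.THREE_PRIME if o == "+" else End.FIVE_PRIME)
            b = EndRef(nid, End.FIVE_PRIME if no == "+" else End.THREE_PRIME)
            support = 2 + int(rng.poisson(depth / 3.0))
            graph.add_edge(ContigEdge(a=a, b=b, support=support))

    # spurious cross-genome links
    all_ids = sorted(graph.nodes)
    by_genome: dict[str, list[str]] = {}
    for cid in all_ids:
        by_genome.setdefault(truth.contig_labels[cid], []).append(cid)
    genomes = sorted(by_genome)
    if len(genomes) < 2:
        cross_links = 0
    injected = 0
    attempts = 0
    while injected < cross_links and attempts < 50 * max(1, cross_links):
        attempts += 1
        ga, gb = rng.choice(genomes, size=2, replace=False)
        ca = by_genome[ga][rng.integers(len(by_genome[ga]))]
        cb = by_genome[gb][rng.integers(len(by_genome[gb]))]
        ea = End.FIVE_PRIME if rng.integers(2) == 0 else End.THREE_PRIME
        eb = End.FIVE_PRIME if rng.integers(2) == 0 else End.THREE_PRIME
        edge = ContigEdge(a=EndRef(ca, ea), b=EndRef(cb, eb), support=1)
        if graph.find_edge(edge.a, edge.b) is None:
            graph.add_edge(edge)
            injected += 1
    return graph, truth


# ---------------------------------------------------------------------------
# Mate-pair link-table simulation
# ---------------------------------------------------------------------------


def simulate_link_table(
    truth: SyntheticTruth,
    n_pairs_per_true_link: int = 50,
    noise_pairs: int = 5,
    seed: int = 0,
) -> LinkTable:
    """Candidate mate-pair links per repeat, true pairings plus noise.

    Each planted flank pairing gets a Poisson(``n_pairs_per_true_link``)
    count; the rows of one alternative (wrong) flank matching get
    Poisson(``noise_pairs``) counts, mirroring the candidate-table shape of
    real mate-pair mapping where spurious pairings attract a few read
    pairs. The selection is only meaningful when noise is well below the
    true signal.
    """
    if noise_pairs >= n_pairs_per_true_link:
        raise ValueError("noise_pairs must be < n_pairs_per_true_link")
    if not truth.link_truth:
        raise ValueError("truth contains no planted repeats; run shred_to_graph first")
    rng = np.random.default_rng(seed)
    table = LinkTable()
    for repeat_id in sorted(truth.link_truth):
        pairings = truth.link_truth[repeat_id]
        for five, three in pairings:
            table.append(
                LinkRecord(
                    repeat_id=repeat_id,
                    five_prime_contig=five,
                    three_prime_contig=three,
                    link_count=int(rng.poisson(n_pairs_per_true_link)),
                )
            )
        fives = [p[0] for p in pairings]
        threes = [p[1] for p in pairings]
        c = len(pairings)
        if c >= 2:
            wrong = [(fives[i], fives[(i + 1) % c]) for i in range(c if c > 2 else 1)]
            wrong += [(threes[i], threes[(i + 1) % c]) for i in range(c if c > 2 else 1)]
            for a, b in wrong:
                table.append(
                    LinkRecord(
                        repeat_id=repeat_id,
                        five_prime_contig=a,
                        three_prime_contig=b,
                        link_count=int(rng.poisson(noise_pairs)),
                    )
                )
    return table


# ---------------------------------------------------------------------------
# Minimal-sequencing-data subsampling experiment
# ---------------------------------------------------------------------------


def subsample_experiment(
    truth: SyntheticTruth,
    read_len: int = 300,
    data_points: Sequence[float] = (),
    seed: int = 0,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Per-genome covered % of organellar positions vs sampled megabases.

    Reads of ``read_len`` bases are drawn from the planted genomes with
    probability proportional to copy-depth-weighted genome mass
    (depth x length), start positions uniform (wrapping on circular
    genomes). For each ascending data point the covered percentage —
    positions hit by at least ``min_cov`` reads — is reported for each
    organellar genome, rounded to 2 decimals. Samples are nested across
    data points (the reads of a smaller sample are a prefix of the larger
    one), so coverage is monotone non-decreasing.
    """
    points = list(data_points)
    if not points:
        raise ValueError("no data points given")
    if sorted(points) != points:
        raise ValueError("data_points must be sorted ascending")
    rng = np.random.default_rng(seed)
    names = sorted(truth.genomes)
    lengths = np.array([len(truth.genomes[n]) for n in names], dtype=float)
    weights = np.array([truth.depths[n] for n in names]) * lengths
    probs = weights / weights.sum()
    organelles = [n for n in names if truth.kinds[n] in (Label.CP, Label.MT)]
    n_reads = [int(round(m * 1e6 / read_len)) for m in points]
    total_reads = n_reads[-1]
    if total_reads:
        assignment = rng.choice(len(names), size=total_reads, p=probs)
        starts = rng.random(total_reads)
    else:
        assignment = np.empty(0, dtype=int)
        starts = np.empty(0)
    cov = {n: np.zeros(len(truth.genomes[n]), dtype=np.int32) for n in organelles}
    org_index = {names.index(n): n for n in organelles}
    rows = []
    done = 0
    for mbp, upto in zip(points, n_reads):
        for j in range(done, upto):
            gi = int(assignment[j])
            name = org_index.get(gi)
            if name is None:
                continue
            L = cov[name].size
            s = int(starts[j] * L)
            e = s + min(read_len, L)
            if e <= L:
                cov[name][s:e] += 1
            else:
                cov[name][s:] += 1
                cov[name][: e - L] += 1
        done = upto
        row = {"sampled_mbp": mbp}
        for name in organelles:
            frac = float((cov[name] >= min_cov).mean())
            row[name] = round(100.0 * frac, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sampled_mbp")


# ---------------------------------------------------------------------------
# One-call dataset preset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    graph: ContigGraph
    truth: SyntheticTruth
    link_table: LinkTable
    cp_reference: dict[str, str]
    mt_reference: dict[str, str]


def default_specs(
    cp_depth: float = DEFAULT_DEPTHS["cp"],
    mt_depth: float = DEFAULT_DEPTHS["mt"],
    nuclear_depth: float = DEFAULT_DEPTHS["nuclear"],
) -> dict[str, GenomeSpec]:
    """Desk-scale defaults: 16 kb quadripartite cp, 40 kb mt with two
    dispersed repeats (one inverted), 200 kb nuclear background in 20
    fragments; class depths as observed in total-DNA leaf sequencing."""
    return {
        "cp": GenomeSpec(kind=Label.CP, copy_depth=cp_depth, gc=0.38,
                         lsc_len=8000, ssc_len=2000, ir_len=3000),
        "mt": GenomeSpec(
            kind=Label.MT,
            copy_depth=mt_depth,
            gc=0.43,
            total_len=40000,
            repeat_specs=(RepeatSpec(600, 2, False), RepeatSpec(450, 2, True)),
        ),
        "nuclear": GenomeSpec(
            kind=Label.NUCLEAR, copy_depth=nuclear_depth, gc=0.36,
            total_len=200000, n_fragments=20,
        ),
    }


def simulate_dataset(
    seed: int,
    specs: Mapping[str, GenomeSpec] | None = None,
    mean_contig_len: int = 1000,
    depth_noise_sd: float = 3.0,
    cross_links: int = 6,
    n_pairs_per_true_link: int = 50,
    noise_pairs: int = 5,
) -> SimulatedDataset:
    """Generate a full planted dataset: graph, truth, links, seed references.

    The reference sequences are 600-base slices of a unique region of each
    planted organellar genome, standing in for conserved organellar genes
    used to seed component extraction.
    """
    specs = dict(specs or default_specs())
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(6)]
    truth = SyntheticTruth()
    _, truth = make_cp_genome(specs["cp"], seeds[0], name="cp", truth=truth)
    _, truth = make_mt_genome(specs["mt"], seeds[1], name="mt", truth=truth)
    truth = make_nuclear_background(specs["nuclear"], seeds[2], truth=truth)
    graph, truth = shred_to_graph(
        truth,
        mean_contig_len=mean_contig_len,
        depth_noise_sd=depth_noise_sd,
        cross_links=cross_links,
        seed=seeds[3],
    )
    link_table = simulate_link_table(
        truth,
        n_pairs_per_true_link=n_pairs_per_true_link,
        noise_pairs=noise_pairs,
        seed=seeds[4],
    )
    cp_ref = {"cp_gene": truth.genomes["cp"][1000:1600]}
    mt_ref = {"mt_gene": truth.genomes["mt"][100:700]}
    return SimulatedDataset(
        graph=graph,
        truth=truth,
        link_table=link_table,
        cp_reference=cp_ref,
        mt_reference=mt_ref,
    )
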