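"""Synthetic communities with known truth.

Generates everything the profiler consumes, fully offline and seeded:
strain genomes derived from a common ancestor by point substitutions
(mutation presets 0.001 and 0.01 per base, mirroring typical within-species
strain divergence), exact variation graphs built from the known variant
positions, reads drawn uniformly along each strain at depths in roughly the
1x-20x range of low-complexity metagenomes, and ground-truth GAF
alignments placing each read on its true path interval. Short reads default
to 150 bp at 0.1% error, long reads to 10 kb at 2% error.

Only substitutions are simulated — no indels or structural variants — which
keeps graph construction exact: every variant site becomes a bubble with
one single-base node per observed allele, and each strain path spells its
genome letter for letter.

A small evaluator (precision/recall/F1 and L1/L2/Bray-Curtis/AFE/RFE
between abundance profiles) makes end-to-end checks self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .align_model import GafRecord
from .graph_model import SuperGraph, VariationGraph, merge_graphs

__all__ = [
    "SimConfig", "SpeciesTruth", "ReadRecord", "TruthSet",
    "simulate_strains", "build_graph_from_variants", "simulate_reads",
    "emit_truth_gaf", "simulate_community", "write_truth_profile",
    "load_profile_tsv", "compare_profiles", "write_fasta", "write_fastq",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """All knobs of the generator; a single seed drives every draw."""

    seed: int = 0
    base_genome_length_bp: int = 100_000
    n_species: int = 1
    strains_per_species: int = 3
    substitution_rate: float = 0.01       # per base, from the ancestor
    per_strain_rates: Optional[Sequence[float]] = None  # overrides the above
    depth_range: tuple[float, float] = (1.0, 20.0)
    depths: Optional[Sequence[float]] = None  # explicit per-strain depths
    read_type: str = "short"              # 'short' or 'long'
    read_length_bp: Optional[int] = None  # default 150 short / 10000 long
    error_rate: Optional[float] = None    # default 0.001 short / 0.02 long
    alignment_noise: float = 0.0          # fraction of reads with a decoy hit
    species_taxids: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.read_type not in ("short", "long"):
            raise ValueError(f"read_type {self.read_type!r}")
        for r in (self.substitution_rate, self.alignment_noise):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.base_genome_length_bp < 1:
            raise ValueError("genome length must be positive")

    @property
    def read_length(self) -> int:
        if self.read_length_bp is not None:
            return self.read_length_bp
        return 150 if self.read_type == "short" else 10_000

    @property
    def read_error_rate(self) -> float:
        if self.error_rate is not None:
            return self.error_rate
        return 0.001 if self.read_type == "short" else 0.02

    def taxid(self, species_index: int) -> int:
        if self.species_taxids is not None:
            return self.species_taxids[species_index]
        return 1000 + species_index


@dataclass
class SpeciesTruth:
    """One species: ancestor, per-strain substitutions, derived genomes."""

    species_taxid: int
    ancestor: str
    alleles: dict[str, dict[int, str]]  # strain -> {position: alt base}

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.alleles)

    def genome(self, strain_id: str) -> str:
        seq = list(self.ancestor)
        for pos, alt in self.alleles[strain_id].items():
            seq[pos] = alt
        return "".join(seq)

    @property
    def variant_positions(self) -> list[int]:
        pos: set[int] = set()
        for muts in self.alleles.values():
            pos.update(muts)
        return sorted(pos)


@dataclass
class ReadRecord:
    read_id: str
    species_taxid: int
    strain_id: str
    start: int      # 0-based on the strain genome (forward coordinates)
    strand: str     # '+' or '-'
    sequence: str   # as sequenced (reverse-complemented for '-' reads)
    n_errors: int


@dataclass
class TruthSet:
    """Everything a pipeline run needs, with the answers attached."""

    config: SimConfig
    species: list[SpeciesTruth]
    graphs: list[VariationGraph]
    supergraph: SuperGraph
    depths: dict[tuple[int, str], float]   # (taxid, strain) -> mean depth
    reads: list[ReadRecord] = field(default_factory=list)

    def relative_abundances(self) -> dict[tuple[int, str], float]:
        total = sum(self.depths.values())
        return {k: v / total for k, v in self.depths.items()}


# ---------------------------------------------------------------------------
# Genomes and graphs
# ---------------------------------------------------------------------------

def simulate_strains(config: SimConfig) -> list[SpeciesTruth]:
    """Ancestors plus per-strain substitution sets, seeded and reproducible.

    Each species gets a uniform-random ancestor; each strain mutates the
    ancestor independently at ``substitution_rate`` per base (or its entry
    in ``per_strain_rates``), always to a different base.
    """
    rng = np.random.default_rng(config.seed)
    rates = config.per_strain_rates
    if rates is not None and len(rates) != config.strains_per_species:
        raise ValueError("per_strain_rates length != strains_per_species")
    out = []
    for si in range(config.n_species):
        taxid = config.taxid(si)
        L = config.base_genome_length_bp
        ancestor = "".join(rng.choice(_BASES, size=L))
        alleles: dict[str, dict[int, str]] = {}
        for j in range(config.strains_per_species):
            rate = rates[j] if rates is not None else config.substitution_rate
            n_mut = rng.binomial(L, rate)
            positions = rng.choice(L, size=n_mut, replace=False)
            muts = {}
            for pos in sorted(int(p) for p in positions):
                ref = ancestor[pos]
                alternatives = [b for b in "ACGT" if b != ref]
                muts[pos] = alternatives[rng.integers(3)]
            alleles[f"S{taxid}.{j + 1}"] = muts
        out.append(SpeciesTruth(species_taxid=taxid, ancestor=ancestor,
                                alleles=alleles))
    return out


def build_graph_from_variants(truth: SpeciesTruth) -> VariationGraph:
    """Exact variation graph from known substitution sites.

    The ancestor backbone is split at every variant position; each site
    becomes a bubble with one single-base node per observed allele. Strain
    paths walk their own alleles, so each path spells its genome exactly.
    """
    graph = VariationGraph(species_taxid=truth.species_taxid)
    positions = truth.variant_positions
    strain_ids = truth.strain_ids

    # observed alleles per site (the ancestor base counts when any strain
    # keeps it)
    site_alleles: dict[int, list[str]] = {}
    for pos in positions:
        seen = {truth.alleles[s].get(pos, truth.ancestor[pos])
                for s in strain_ids}
        site_alleles[pos] = sorted(seen)

    next_id = 1
    backbone_node: dict[int, int] = {}   # backbone segment start -> node id
    allele_node: dict[tuple[int, str], int] = {}

    bounds = [0] + [p for pos in positions for p in (pos, pos + 1)] + \
             [len(truth.ancestor)]
    variant_set = set(positions)
    for start, end in zip(bounds, bounds[1:]):
        if end <= start:
            continue
        if start in variant_set and end == start + 1:
            for base in site_alleles[start]:
                graph.add_node(next_id, base)
                allele_node[(start, base)] = next_id
                next_id += 1
        else:
            graph.add_node(next_id, truth.ancestor[start:end])
            backbone_node[start] = next_id
            next_id += 1

    for sid in strain_ids:
        steps = []
        for start, end in zip(bounds, bounds[1:]):
            if end <= start:
                continue
            if start in variant_set and end == start + 1:
                base = truth.alleles[sid].get(start, truth.ancestor[start])
                steps.append((allele_node[(start, base)], "+"))
            else:
                steps.append((backbone_node[start], "+"))
        graph.add_path(sid, steps, add_missing_edges=True)
    return graph


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _assign_depths(truth: Sequence[SpeciesTruth], config: SimConfig,
                   rng: np.random.Generator) -> dict[tuple[int, str], float]:
    depths: dict[tuple[int, str], float] = {}
    for sp in truth:
        for j, sid in enumerate(sp.strain_ids):
            if config.depths is not None:
                d = float(config.depths[j])
            else:
                d = float(rng.uniform(*config.depth_range))
            depths[(sp.species_taxid, sid)] = d
    return depths


def simulate_reads(truth: Sequence[SpeciesTruth], config: SimConfig,
                   depths: Mapping[tuple[int, str], float],
                   rng: Optional[np.random.Generator] = None
                   ) -> list[ReadRecord]:
    """Uniformly placed reads per strain at its assigned mean depth.

    Read count per strain = round(depth * genome_length / read_length);
    starts uniform, strands equiprobable, per-base substitution errors at
    the configured rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    err = config.read_error_rate
    reads: list[ReadRecord] = []
    counter = 0
    for sp in truth:
        for sid in sp.strain_ids:
            genome = sp.genome(sid)
            if rl > len(genome):
                raise ValueError(
                    f"read length {rl} exceeds genome length {len(genome)}")
            depth = depths[(sp.species_taxid, sid)]
            n_reads = int(round(depth * len(genome) / rl))
            for _ in range(n_reads):
                start = int(rng.integers(0, len(genome) - rl + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                seq = genome[start:start + rl]
                n_err = int(rng.binomial(rl, err)) if err > 0 else 0
                if n_err:
                    pos = rng.choice(rl, size=n_err, replace=False)
                    s = list(seq)
                    for p in pos:
                        s[p] = "ACGT"[(("ACGT".index(s[p])
                                        + int(rng.integers(1, 4))) % 4)]
                    seq = "".join(s)
                if strand == "-":
                    seq = _revcomp(seq)
                counter += 1
                reads.append(ReadRecord(
                    read_id=f"r{counter}", species_taxid=sp.species_taxid,
                    strain_id=sid, start=start, strand=strand,
                    sequence=seq, n_errors=n_err))
    return reads


# ---------------------------------------------------------------------------
# Ground-truth GAF emission
# ---------------------------------------------------------------------------

def _subpath_for_interval(graph: VariationGraph, strain_id: str,
                          start: int, end: int
                          ) -> tuple[list[tuple[int, str]], int, int]:
    """Steps of the strain path overlapping genome interval [start, end),
    plus the interval's offsets relative to the subpath."""
    steps = graph.paths[strain_id].steps
    sub = []
    offset = 0
    first_offset = None
    for v, o in steps:
        ln = graph.nodes[v].length_bp
        if offset + ln > start and offset < end:
            if first_offset is None:
                first_offset = offset
            sub.append((v, o))
        offset += ln
        if offset >= end:
            break
    assert first_offset is not None
    return sub, start - first_offset, end - first_offset


def _placement_multiplicity(graph: VariationGraph,
                            node_seq: Sequence[int],
                            path_strings: Mapping[str, str]) -> int:
    """How many strain paths of the species contain this node sequence
    contiguously (either direction)."""
    fwd = "|" + "|".join(map(str, node_seq)) + "|"
    rev = "|" + "|".join(map(str, reversed(node_seq))) + "|"
    count = 0
    for s in path_strings.values():
        if fwd in s or rev in s:
            count += 1
    return count


def emit_truth_gaf(reads: Sequence[ReadRecord], truth: TruthSet,
                   rng: Optional[np.random.Generator] = None
                   ) -> list[GafRecord]:
    """Place each read on its true path interval; emit optional decoys.

    The MAPQ model reflects placement ambiguity within the species: 60 when
    the read's node interval is consistent with exactly one strain path,
    3 with two, 0 with more. With ``alignment_noise`` > 0, that fraction of
    reads additionally emits one strictly lower-scoring decoy alignment on
    a random other strain path.
    """
    config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    graphs = {g.species_taxid: g for g in truth.supergraph.species_graphs}
    path_strings = {
        taxid: {sid: "|" + "|".join(str(v) for v, _ in p.steps) + "|"
                for sid, p in g.paths.items()}
        for taxid, g in graphs.items()}
    all_paths = [(taxid, sid) for taxid, g in graphs.items()
                 for sid in g.paths]

    records: list[GafRecord] = []
    for read in reads:
        g = graphs[read.species_taxid]
        rl = len(read.sequence)
        sub, s_off, e_off = _subpath_for_interval(
            g, read.strain_id, read.start, read.start + rl)
        sub_len = sum(g.nodes[v].length_bp for v, _ in sub)
        if read.strand == "-":
            steps = [(v, "-" if o == "+" else "+") for v, o in reversed(sub)]
            p_start, p_end = sub_len - e_off, sub_len - s_off
        else:
            steps = sub
            p_start, p_end = s_off, e_off
        matches = rl - read.n_errors
        mult = _placement_multiplicity(
            g, [v for v, _ in sub], path_strings[read.species_taxid])
        mapq = 60 if mult <= 1 else (3 if mult == 2 else 0)
        records.append(GafRecord(
            read_id=read.read_id, read_length=rl, read_start=0, read_end=rl,
            strand="+", path_steps=steps, path_length=sub_len,
            path_start=p_start, path_end=p_end, residue_matches=matches,
            block_length=rl, mapq=mapq,
            tags={"AS": ("i", str(matches))}))

        if config.alignment_noise > 0 and rng.random() < config.alignment_noise:
            d_taxid, d_sid = all_paths[int(rng.integers(len(all_paths)))]
            if (d_taxid, d_sid) == (read.species_taxid, read.strain_id):
                continue
            dg = graphs[d_taxid]
            glen = dg.path_length_bp(d_sid)
            span = min(rl, glen)
            d_start = int(rng.integers(0, glen - span + 1))
            dsub, ds, de = _subpath_for_interval(dg, d_sid, d_start,
                                                 d_start + span)
            dlen = sum(dg.nodes[v].length_bp for v, _ in dsub)
            decoy_score = max(0, matches - 10)
            records.append(GafRecord(
                read_id=read.read_id, read_length=rl, read_start=0,
                read_end=span, strand="+", path_steps=dsub,
                path_length=dlen, path_start=ds, path_end=de,
                residue_matches=decoy_score, block_length=span, mapq=0,
                tags={"AS": ("i", str(decoy_score))}))
    return records


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def simulate_community(config: SimConfig) -> TruthSet:
    """Genomes -> graphs -> super-graph -> depths -> reads, one call."""
    species = simulate_strains(config)
    graphs = [build_graph_from_variants(sp) for sp in species]
    supergraph = merge_graphs(graphs)
    rng = np.random.default_rng(config.seed + 1)
    depths = _assign_depths(species, config, rng)
    truth = TruthSet(config=config, species=species, graphs=graphs,
                     supergraph=supergraph, depths=depths)
    truth.reads = simulate_reads(species, config, depths, rng)
    return truth


# ---------------------------------------------------------------------------
# Truth profile and evaluation metrics
# ---------------------------------------------------------------------------

def write_truth_profile(truth: TruthSet, dest) -> str:
    """Truth profile in the same TSV schema as the predicted strain profile."""
    total = sum(truth.depths.values())
    lines = ["species_taxid\tstrain_id\tpredicted_coverage\trelative_abundance"]
    for (taxid, sid) in sorted(truth.depths):
        d = truth.depths[(taxid, sid)]
        lines.append(f"{taxid}\t{sid}\t{d:.6g}\t{d / total:.6g}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
    return text


def load_profile_tsv(source) -> dict[tuple[int, str], float]:
    """Load a strain-profile TSV into {(taxid, strain): relative_abundance}."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    out: dict[tuple[int, str], float] = {}
    for line in lines[1:]:
        if not line:
            continue
        taxid, sid, _ab, rel = line.split("\t")
        out[(int(taxid), sid)] = float(rel)
    return out


def compare_profiles(truth: Mapping, predicted: Mapping) -> dict[str, float]:
    """Detection and abundance metrics between two relative-abundance maps.

    Keys are taxa (any hashable); values are relative abundances. Returns
    precision/recall/F1 on the presence calls and L1, L2, Bray-Curtis, AFE
    (mean absolute frequency error) and RFE (mean bounded relative error
    |p-t|/max(p,t)) over the union of taxa.
    """
    t_set = {k for k, v in truth.items() if v > 0}
    p_set = {k for k, v in predicted.items() if v > 0}
    tp = len(t_set & p_set)
    precision = tp / len(p_set) if p_set else 0.0
    recall = tp / len(t_set) if t_set else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    union = sorted(t_set | p_set, key=repr)
    t = np.array([truth.get(k, 0.0) for k in union])
    p = np.array([predicted.get(k, 0.0) for k in union])
    diff = np.abs(p - t)
    denom = np.maximum(p, t)
    rel_err = np.where(denom > 0, diff / np.where(denom > 0, denom, 1), 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "l1": float(diff.sum()),
        "l2": float(math.sqrt(((p - t) ** 2).sum())),
        "braycurtis": float(diff.sum() / (p + t).sum()) if len(union) else 0.0,
        "afe": float(diff.mean()) if len(union) else 0.0,
        "rfe": float(rel_err.mean()) if len(union) else 0.0,
    }


# ---------------------------------------------------------------------------
# FASTA / FASTQ output (Biopython-backed)
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], dest) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sequences.items()]
    if hasattr(dest, "write"):
        seqio_write(recs, dest, "fasta")
    else:
        with open(dest, "w") as fh:
            seqio_write(recs, fh, "fasta")


def write_fastq(reads: Iterable[ReadRecord], dest) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [30] * len(r.sequence)
        recs.append(rec)
    if hasattr(dest, "write"):
        seqio_write(recs, dest, "fastq")
    else:
        with open(dest, "w") as fh:
            seqio_write(recs, fh, "fastq")
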