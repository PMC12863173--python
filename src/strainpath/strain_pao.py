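"""Strain abundance by path-abundance optimization (PAO).

Within one species graph, every strain path implies a node-depth profile:
a strain present at mean depth *a* contributes *a* to each node it
traverses (per visit). Observed per-node depths are computed by projecting
read alignments onto segments; PAO then finds non-negative per-strain
abundances minimizing the length-weighted L1 discrepancy

    minimize  sum_v w_v * | cov_v - sum_p m_p(v) * a_p |,   a_p >= 0,

with w_v = len_v / sum_u len_u and m_p(v) the path's visit count of node v.
The absolute values linearize exactly, so the problem is an LP (solved with
HiGHS via scipy).

Two PAO iterations run, each preceded by a filter:

* stage 1 — f_strain, the covered fraction of the strain's *specific
  triplets* (consecutive node triples occurring in no other strain of the
  species), must reach 0.3 (short reads) / 0.5 (long reads);
* stage 2 — d_strain, the divergence between the PAO estimate a_p and an
  independent triplet-based depth estimate a_p,triplet, must be <= 0.46;
  strains at 0.46 < d <= 0.6 are rescued when r_strain = b_strain *
  f_strain >= 0.85 (b_strain = breadth of coverage of the strain path).
  Rescued strains report min(a_p, a_p,triplet).

Finally, per-species consistency: species whose summed strain abundances
diverge from the species-level depth estimate by more than 0.2 are removed;
strain sums exceeding the species estimate are proportionally scaled down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.sparse import eye as sparse_eye
from scipy.sparse import hstack as sparse_hstack
from scipy.sparse import vstack as sparse_vstack

from .align_model import GafRecord
from .graph_model import (VariationGraph, Triplet, canonical_triple,
                          enumerate_strain_specific_triplets)

__all__ = [
    "StrainConfig", "NodeCoverage", "PaoProblem", "StrainEstimate",
    "SpeciesConsistency", "StrainProfile",
    "compute_node_coverage", "solve_pao", "compute_f_strain",
    "compute_a_triplet", "compute_b_strain", "compute_d_strain",
    "filter_stage1", "filter_stage2", "iterate_pao",
    "species_consistency_filter", "finalize_profile", "write_strain_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class StrainConfig:
    """Thresholds and numerical settings of the strain-level cascade."""

    f_min_short: float = 0.3    # stage-1 f_strain cutoff, short reads
    f_min_long: float = 0.5     # stage-1 f_strain cutoff, long reads
    d_max: float = 0.46         # stage-2 retention cutoff on d_strain
    d_rescue_max: float = 0.6   # rescue window upper bound on d_strain
    r_min: float = 0.85         # rescue requirement on r = b * f
    d_species_max: float = 0.2  # species-consistency cutoff
    f_mode: str = "traversal"   # 'traversal' or 'nodes' triplet coverage
    solver_tolerance: float = 1e-6


# ---------------------------------------------------------------------------
# Node coverage
# ---------------------------------------------------------------------------

@dataclass
class NodeCoverage:
    """Per-node aligned-base counts for one species graph."""

    graph: VariationGraph
    aligned_bases: dict[int, int] = field(default_factory=dict)

    def depth(self, node_id: int) -> float:
        return (self.aligned_bases.get(node_id, 0)
                / self.graph.nodes[node_id].length_bp)

    def is_covered(self, node_id: int) -> bool:
        return self.aligned_bases.get(node_id, 0) > 0


def compute_node_coverage(graph: VariationGraph,
                          alignments: Iterable[GafRecord]) -> NodeCoverage:
    """Project alignment path intervals onto segment nodes.

    For each record, the path interval [start, end) is intersected with the
    base span of every step along the concatenated path; overlapping bases
    accrue to that node. Repeated nodes accumulate once per visit.
    Orientation does not matter for base counting.
    """
    cov = NodeCoverage(graph=graph)
    for rec in alignments:
        if not rec.is_mapped:
            continue
        total = sum(graph.nodes[v].length_bp for v, _ in rec.path_steps)
        if not (0 <= rec.path_start < rec.path_end <= total):
            raise ValueError(
                f"read {rec.read_id}: path interval "
                f"[{rec.path_start},{rec.path_end}) outside [0,{total})")
        offset = 0
        for v, _ in rec.path_steps:
            ln = graph.nodes[v].length_bp
            lo = max(rec.path_start, offset)
            hi = min(rec.path_end, offset + ln)
            if hi > lo:
                cov.aligned_bases[v] = cov.aligned_bases.get(v, 0) + (hi - lo)
            offset += ln
            if offset >= rec.path_end:
                break
    return cov


# ---------------------------------------------------------------------------
# The PAO linear program
# ---------------------------------------------------------------------------

@dataclass
class PaoProblem:
    """One PAO instance: node depths vs candidate-path multiplicities."""

    node_ids: list[int]
    lengths: np.ndarray          # len_v per node, aligned with node_ids
    depths: np.ndarray           # cov_v per node
    strain_ids: list[str]
    multiplicity: np.ndarray     # (n_nodes, n_strains) visit counts

    @classmethod
    def from_graph(cls, graph: VariationGraph, coverage: NodeCoverage,
                   candidates: Sequence[str]) -> "PaoProblem":
        """Build the LP over the union of the candidate paths' nodes."""
        strain_ids = sorted(candidates)
        node_set: set[int] = set()
        for sid in strain_ids:
            node_set.update(v for v, _ in graph.paths[sid].steps)
        node_ids = sorted(node_set)
        idx = {v: i for i, v in enumerate(node_ids)}
        lengths = np.array([graph.nodes[v].length_bp for v in node_ids], float)
        depths = np.array([coverage.depth(v) for v in node_ids], float)
        mult = np.zeros((len(node_ids), len(strain_ids)))
        for j, sid in enumerate(strain_ids):
            for v, cnt in graph.paths[sid].node_multiplicity().items():
                mult[idx[v], j] = cnt
        return cls(node_ids, lengths, depths, strain_ids, mult)

    @property
    def weights(self) -> np.ndarray:
        return self.lengths / self.lengths.sum()

    def objective(self, abundances: np.ndarray) -> float:
        """Length-weighted L1 residual for a given abundance vector."""
        resid = self.depths - self.multiplicity @ abundances
        return float(self.weights @ np.abs(resid))


def solve_pao(problem: PaoProblem,
              solver_tolerance: float = 1e-6) -> dict[str, float]:
    """Solve the PAO LP; returns strain_id -> estimated mean depth a_p.

    Standard absolute-value linearization: auxiliary e_v >= +-(cov_v - M a)
    with objective sum_v w_v e_v, a >= 0. Deterministic for a fixed solver.
    """
    n_v, n_p = problem.multiplicity.shape
    if n_p < 1:
        raise ValueError("PAO needs at least one candidate path")
    if not np.all(np.isfinite(problem.depths)):
        raise ValueError("non-finite node depth")
    # variables: [a_1..a_P, e_1..e_V]
    c = np.concatenate([np.zeros(n_p), problem.weights])
    M = csr_matrix(problem.multiplicity)
    eye = sparse_eye(n_v, format="csr")
    # M a + e >= cov  ->  -M a - e <= -cov
    # M a - e <= cov
    A_ub = sparse_vstack([sparse_hstack([-M, -eye]),
                          sparse_hstack([M, -eye])], format="csr")
    b_ub = np.concatenate([-problem.depths, problem.depths])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(0, None)] * (n_p + n_v),
                  method="highs",
                  options={"primal_feasibility_tolerance": solver_tolerance,
                           "dual_feasibility_tolerance": solver_tolerance})
    if not res.success:
        raise RuntimeError(f"PAO solver failed: {res.message}")
    a = np.maximum(res.x[:n_p], 0.0)
    return dict(zip(problem.strain_ids, a.tolist()))


# ---------------------------------------------------------------------------
# Per-strain statistics
# ---------------------------------------------------------------------------

def compute_f_strain(graph: VariationGraph, strain_id: str,
                     coverage: NodeCoverage,
                     alignments: Optional[Iterable[GafRecord]] = None,
                     mode: str = "traversal",
                     triplets: Optional[set[Triplet]] = None) -> float:
    """Covered fraction of the strain's specific triplets, in [0, 1].

    mode 'traversal' (default): a triplet counts as covered iff some single
    alignment's path walks the oriented triple consecutively (either
    direction). mode 'nodes': covered iff all three member nodes have
    nonzero coverage. A strain with no specific triplets gets f = 0.
    """
    if triplets is None:
        triplets = enumerate_strain_specific_triplets(graph, strain_id)
    if not triplets:
        return 0.0
    if mode == "nodes":
        covered = sum(
            1 for t in triplets
            if all(coverage.is_covered(v) for v, _ in t.steps))
    elif mode == "traversal":
        if alignments is None:
            raise ValueError("traversal mode needs the alignments")
        seen: set[tuple] = set()
        for rec in alignments:
            s = rec.path_steps
            for i in range(len(s) - 2):
                seen.add(canonical_triple((s[i], s[i + 1], s[i + 2])))
        covered = sum(1 for t in triplets if canonical_triple(t.steps) in seen)
    else:
        raise ValueError(f"unknown f_strain mode {mode!r}")
    return covered / len(triplets)


def compute_a_triplet(graph: VariationGraph, strain_id: str,
                      coverage: NodeCoverage,
                      triplets: Optional[set[Triplet]] = None) -> float:
    """Triplet-based depth estimate, independent of the LP.

    Length-weighted mean depth over the distinct nodes participating in the
    strain's specific triplets, restricted to nodes traversed by no other
    path of the species: shared nodes carry the summed depth of every
    co-occurring strain, so only strain-exclusive nodes estimate this
    strain's own depth. Falls back to all triplet nodes when the strain's
    specific triplets consist purely of shared nodes in a novel order;
    0 when the strain has no specific triplets.
    """
    if triplets is None:
        triplets = enumerate_strain_specific_triplets(graph, strain_id)
    nodes = {v for t in triplets for v, _ in t.steps}
    if not nodes:
        return 0.0
    shared: set[int] = set()
    for sid, path in graph.paths.items():
        if sid != strain_id:
            shared.update(v for v, _ in path.steps)
    exclusive = nodes - shared
    use = exclusive if exclusive else nodes
    total_len = sum(graph.nodes[v].length_bp for v in use)
    total_bases = sum(coverage.aligned_bases.get(v, 0) for v in use)
    return total_bases / total_len


def compute_b_strain(graph: VariationGraph, strain_id: str,
                     coverage: NodeCoverage) -> float:
    """Breadth of coverage: fraction of strain-path bases on covered nodes."""
    path = graph.paths[strain_id]
    total = covered = 0
    for v, _ in path.steps:
        ln = graph.nodes[v].length_bp
        total += ln
        if coverage.is_covered(v):
            covered += ln
    return covered / total


def compute_d_strain(a_p: float, a_p_triplet: float) -> float:
    """Normalized divergence |a_p - a_p,triplet| / max of the two; 0 at 0/0."""
    if a_p < 0 or a_p_triplet < 0:
        raise ValueError("abundance estimates must be non-negative")
    m = max(a_p, a_p_triplet)
    return abs(a_p - a_p_triplet) / m if m > 0 else 0.0


# ---------------------------------------------------------------------------
# Filter cascade and the two PAO iterations
# ---------------------------------------------------------------------------

@dataclass
class StrainEstimate:
    """All per-strain statistics and filter outcomes for one candidate."""

    strain_id: str
    f_strain: float = 0.0
    a_p: float = 0.0
    a_p_triplet: float = 0.0
    b_strain: float = 0.0
    d_strain: float = 0.0
    passed_stage1: bool = False
    passed_stage2: bool = False
    rescued: bool = False
    reported_abundance: float = 0.0

    @property
    def r_strain(self) -> float:
        return self.b_strain * self.f_strain

    @property
    def retained(self) -> bool:
        return self.passed_stage2 or self.rescued


def filter_stage1(estimates: Iterable[StrainEstimate], read_type: str,
                  config: StrainConfig = StrainConfig()) -> list[StrainEstimate]:
    """Retain strains whose f_strain reaches the read-type threshold."""
    if read_type == "short":
        cutoff = config.f_min_short
    elif read_type == "long":
        cutoff = config.f_min_long
    else:
        raise ValueError(f"unknown read_type {read_type!r}")
    survivors = []
    for est in estimates:
        est.passed_stage1 = est.f_strain >= cutoff
        if est.passed_stage1:
            survivors.append(est)
    return survivors


def filter_stage2(estimates: Iterable[StrainEstimate],
                  config: StrainConfig = StrainConfig()) -> list[StrainEstimate]:
    """Retain at d <= 0.46; rescue at 0.46 < d <= 0.6 when r = b*f >= 0.85."""
    survivors = []
    for est in estimates:
        est.passed_stage2 = est.d_strain <= config.d_max
        est.rescued = (not est.passed_stage2
                       and est.d_strain <= config.d_rescue_max
                       and est.r_strain >= config.r_min)
        if est.passed_stage2 or est.rescued:
            survivors.append(est)
    return survivors


def iterate_pao(graph: VariationGraph, coverage: NodeCoverage,
                alignments: Sequence[GafRecord],
                candidates: Optional[Sequence[str]] = None,
                read_type: str = "short",
                config: StrainConfig = StrainConfig()) -> list[StrainEstimate]:
    """The full two-iteration PAO cascade for one species.

    Pipeline: stage-1 filter on f_strain -> PAO #1 over survivors ->
    stage-2 filter/rescue on (d_strain, r_strain) -> PAO #2 over the final
    survivors. Reported abundance is the PAO #2 estimate, except rescued
    strains report min(a_p, a_p,triplet). Estimates for *all* candidates
    are returned, filtered ones with reported_abundance 0 and flags unset.
    """
    if candidates is None:
        candidates = sorted(graph.paths)
    triplet_cache = {sid: enumerate_strain_specific_triplets(graph, sid)
                     for sid in candidates}
    estimates = []
    for sid in sorted(candidates):
        est = StrainEstimate(strain_id=sid)
        est.f_strain = compute_f_strain(
            graph, sid, coverage, alignments=alignments, mode=config.f_mode,
            triplets=triplet_cache[sid])
        est.b_strain = compute_b_strain(graph, sid, coverage)
        estimates.append(est)

    stage1 = filter_stage1(estimates, read_type, config)
    if not stage1:
        return estimates

    abund1 = solve_pao(
        PaoProblem.from_graph(graph, coverage, [e.strain_id for e in stage1]),
        config.solver_tolerance)
    for est in stage1:
        est.a_p = abund1[est.strain_id]
        est.a_p_triplet = compute_a_triplet(
            graph, est.strain_id, coverage, triplets=triplet_cache[est.strain_id])
        est.d_strain = compute_d_strain(est.a_p, est.a_p_triplet)

    stage2 = filter_stage2(stage1, config)
    if not stage2:
        return estimates

    abund2 = solve_pao(
        PaoProblem.from_graph(graph, coverage, [e.strain_id for e in stage2]),
        config.solver_tolerance)
    for est in stage2:
        est.a_p = abund2[est.strain_id]
        est.reported_abundance = (min(est.a_p, est.a_p_triplet)
                                  if est.rescued else est.a_p)
    return estimates


# ---------------------------------------------------------------------------
# Species consistency and the final profile
# ---------------------------------------------------------------------------

@dataclass
class SpeciesConsistency:
    species_taxid: int
    species_abundance: float   # A_i = c_i
    strain_sum: float          # S_i before scaling
    d_species: float
    removed: bool
    scaled: bool


def species_consistency_filter(
    species_coverage: Mapping[int, float],
    estimates_by_species: Mapping[int, Sequence[StrainEstimate]],
    config: StrainConfig = StrainConfig(),
) -> tuple[list[SpeciesConsistency], dict[tuple[int, str], float]]:
    """Cross-check strain sums against species-level depth estimates.

    d_species = |A_i - S_i| / max(A_i, S_i) (0 at 0/0). Species above the
    cutoff are removed with all their strains; where S_i > A_i for a
    retained species, strain abundances are scaled by A_i / S_i so that the
    strain sum equals the species estimate exactly.
    """
    records: list[SpeciesConsistency] = []
    adjusted: dict[tuple[int, str], float] = {}
    for taxid in sorted(species_coverage):
        a_i = species_coverage[taxid]
        kept = [e for e in estimates_by_species.get(taxid, []) if e.retained]
        s_i = sum(e.reported_abundance for e in kept)
        m = max(a_i, s_i)
        d = abs(a_i - s_i) / m if m > 0 else 0.0
        removed = d > config.d_species_max
        scale_needed = (not removed) and s_i > a_i and s_i > 0
        records.append(SpeciesConsistency(
            species_taxid=taxid, species_abundance=a_i, strain_sum=s_i,
            d_species=d, removed=removed, scaled=scale_needed))
        if removed:
            if kept:
                logger.warning(
                    "species %d removed by consistency filter "
                    "(d_species=%.3f > %.2f)", taxid, d, config.d_species_max)
            continue
        if not kept:
            logger.warning(
                "species %d has no surviving strain; kept in the species "
                "profile only", taxid)
            continue
        factor = a_i / s_i if scale_needed else 1.0
        for e in kept:
            adjusted[(taxid, e.strain_id)] = e.reported_abundance * factor
    return records, adjusted


@dataclass
class StrainProfile:
    """Final report: one row per strain, sorted by (taxid, strain_id)."""

    rows: list[tuple[int, str, float, float]]
    # (species_taxid, strain_id, absolute_abundance, relative_abundance)

    @property
    def is_empty(self) -> bool:
        return not self.rows


def finalize_profile(
        abundances: Mapping[tuple[int, str], float]) -> StrainProfile:
    """Normalize absolute strain abundances into the final profile."""
    total = sum(abundances.values())
    rows = []
    for (taxid, sid) in sorted(abundances):
        ab = abundances[(taxid, sid)]
        rows.append((taxid, sid, ab, ab / total if total > 0 else 0.0))
    return StrainProfile(rows=rows)


def write_strain_profile(profile: StrainProfile, dest) -> str:
    lines = ["species_taxid\tstrain_id\tpredicted_coverage\trelative_abundance"]
    for taxid, sid, ab, rel in profile.rows:
        lines.append(f"{taxid}\t{sid}\t{ab:.6g}\t{rel:.6g}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
    return text
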