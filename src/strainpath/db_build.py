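"""Reference-database construction: dereplication and fast pre-filtering.

Redundant strain genomes inflate graph complexity without adding signal, so
genomes of a species are dereplicated by single-linkage clustering on
pairwise ANI (average nucleotide identity, percent) and capped at a fixed
number of representatives per species. The canonical two-pass scheme
clusters at 95% (species-level redundancy) and then 99.9% (near-identical
strains); both thresholds are exposed.

A *fast mode* pre-filter sketches each genome's k-mers (FracMinHash) and
estimates its ANI to the read sample from k-mer containment, discarding
database strains clearly absent from the sample before any graph is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord", "AniMatrix", "single_linkage_clusters",
    "select_representatives", "dereplicate",
    "KmerSketch", "sketch_containment_ani", "fast_filter",
    "read_genome_table", "read_ani_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class GenomeRecord:
    accession: str
    species_taxid: int
    sequence: str
    is_plasmid: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")


class AniMatrix:
    """Symmetric pairwise-ANI lookup over a genome list.

    Directed entries are symmetrized by taking the larger of the two values
    (as the underlying aligners report slightly asymmetric estimates);
    missing pairs behave as below any threshold. Diagonal is 100.
    """

    def __init__(self, accessions: Sequence[str],
                 entries: Mapping[tuple[str, str], float] = ()):
        self.accessions = list(accessions)
        self._idx = {a: i for i, a in enumerate(self.accessions)}
        if len(self._idx) != len(self.accessions):
            raise ValueError("duplicate accessions")
        n = len(self.accessions)
        self._m = np.full((n, n), np.nan)
        np.fill_diagonal(self._m, 100.0)
        for (a, b), v in dict(entries).items():
            self.set(a, b, v)

    def set(self, a: str, b: str, value: float) -> None:
        if np.isnan(value):
            raise ValueError(f"NaN ANI entry for ({a}, {b})")
        if not (0.0 <= value <= 100.0):
            raise ValueError(f"ANI {value} outside [0, 100]")
        i, j = self._idx[a], self._idx[b]
        if i == j:
            return
        cur = self._m[i, j]
        v = value if np.isnan(cur) else max(cur, value)
        self._m[i, j] = self._m[j, i] = v

    def get(self, a: str, b: str) -> float:
        """ANI of a pair; NaN for missing (treated as below any threshold)."""
        return float(self._m[self._idx[a], self._idx[b]])

    def pairs_at_least(self, threshold: float) -> list[tuple[str, str]]:
        out = []
        n = len(self.accessions)
        for i in range(n):
            for j in range(i + 1, n):
                if self._m[i, j] >= threshold:  # NaN compares False
                    out.append((self.accessions[i], self.accessions[j]))
        return out


def read_ani_tsv(source, accessions: Optional[Sequence[str]] = None) -> AniMatrix:
    """Load an ANI matrix from TSV.

    Accepts either long form (three columns: query, reference, ani) or a
    square matrix with accession row/column labels.
    """
    df = pd.read_csv(source, sep="\t")
    if df.shape[1] == 3 and not set(df.columns[1:]).issubset(df.iloc[:, 0]):
        accs = list(accessions) if accessions is not None else sorted(
            set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        m = AniMatrix(accs)
        for _, (a, b, v) in df.iterrows():
            m.set(str(a), str(b), float(v))
        return m
    df = pd.read_csv(source, sep="\t", index_col=0)
    accs = [str(a) for a in df.index]
    m = AniMatrix(accs)
    for a in accs:
        for b in accs:
            if a != b and not pd.isna(df.loc[a, b]):
                m.set(a, b, float(df.loc[a, b]))
    return m


def read_genome_table(source) -> pd.DataFrame:
    """Genome metadata TSV: accession, species_taxid, optional is_plasmid."""
    df = pd.read_csv(source, sep="\t", dtype={"accession": str})
    required = {"accession", "species_taxid"}
    if not required.issubset(df.columns):
        raise ValueError(f"genome table needs columns {sorted(required)}")
    if "is_plasmid" in df.columns:
        df = df[~df["is_plasmid"].astype(bool)].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Single-linkage dereplication
# ---------------------------------------------------------------------------

def single_linkage_clusters(ani: AniMatrix,
                            threshold_pct: float) -> list[list[str]]:
    """Connected components of the >=threshold ANI graph (single linkage).

    Clusters are sorted by their smallest member accession, members sorted
    within each cluster — fully deterministic.
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    g = nx.Graph()
    g.add_nodes_from(ani.accessions)
    g.add_edges_from(ani.pairs_at_least(threshold_pct))
    clusters = [sorted(c) for c in nx.connected_components(g)]
    return sorted(clusters, key=lambda c: c[0])


def select_representatives(
    clusters: Sequence[Sequence[str]],
    ani: AniMatrix,
    cap: Optional[int] = 10,
    genome_lengths: Optional[Mapping[str, int]] = None,
) -> list[str]:
    """One representative per cluster, at most ``cap`` per species call.

    Within a cluster the genome with the highest mean ANI to its cluster
    mates wins (ties: longer genome, then smaller accession). When more
    than ``cap`` clusters exist, the ``cap`` largest clusters are kept
    (ties: smaller lead accession).
    """
    lengths = genome_lengths or {}

    def rep_of(cluster: Sequence[str]) -> str:
        if len(cluster) == 1:
            return cluster[0]
        def score(acc: str):
            vals = [ani.get(acc, other) for other in cluster if other != acc]
            mean = float(np.nanmean([v if not np.isnan(v) else 0.0
                                     for v in vals]))
            return (-mean, -lengths.get(acc, 0), acc)
        return min(cluster, key=score)

    ordered = sorted(clusters, key=lambda c: (-len(c), sorted(c)[0]))
    kept = ordered[:cap] if cap is not None else ordered
    reps = [rep_of(c) for c in kept]
    return sorted(reps)


def dereplicate(genomes: Sequence[GenomeRecord], ani: AniMatrix,
                thresholds_pct: Sequence[float] = (95.0, 99.9),
                cap: int = 10) -> list[GenomeRecord]:
    """Sequential clustering passes (default 95% then 99.9%) with a cap.

    Each pass clusters the survivors of the previous pass and keeps one
    representative per cluster; the per-species cap applies on the final
    pass. Plasmid-flagged records are dropped first.
    """
    by_acc = {g.accession: g for g in genomes if not g.is_plasmid}
    survivors = sorted(by_acc)
    for k, thr in enumerate(thresholds_pct):
        sub = AniMatrix(survivors)
        for i, a in enumerate(survivors):
            for b in survivors[i + 1:]:
                v = ani.get(a, b)
                if not np.isnan(v):
                    sub.set(a, b, v)
        clusters = single_linkage_clusters(sub, thr)
        last = k == len(thresholds_pct) - 1
        survivors = select_representatives(
            clusters, sub, cap=cap if last else None,
            genome_lengths={a: by_acc[a].length_bp for a in survivors})
    return [by_acc[a] for a in survivors]


# ---------------------------------------------------------------------------
# FracMinHash containment ANI (fast-mode pre-filter)
# ---------------------------------------------------------------------------

_MASK64 = (1 << 64) - 1
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _hash64(kmer: str, seed: int) -> int:
    # splitmix64 over a seed-dependent fingerprint of the k-mer; cheap,
    # well-mixed, and reproducible across platforms
    z = 0
    for ch in kmer.encode():
        z = ((z * 131) + ch) & _MASK64
    z = (z + 0x9E3779B97F4A7C15 * (seed + 1)) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def _canonical_kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    rc = _revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        rev = rc[n - k - i:n - i]
        if "N" in fwd:
            continue
        yield min(fwd, rev)


@dataclass
class KmerSketch:
    """FracMinHash sketch: canonical k-mers whose hash clears 1/scale."""

    k: int
    scale: int
    seed: int
    hashes: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def from_sequence(cls, seq: str, k: int = 21, scale: int = 1000,
                      seed: int = 42) -> "KmerSketch":
        if len(seq) < k:
            raise ValueError(f"sequence shorter than k={k}")
        limit = _MASK64 // scale
        kept = {h for kmer in _canonical_kmers(seq, k)
                if (h := _hash64(kmer, seed)) <= limit}
        return cls(k=k, scale=scale, seed=seed, hashes=frozenset(kept))

    @classmethod
    def from_reads(cls, reads: Iterable[str], k: int = 21, scale: int = 1,
                   seed: int = 42) -> "KmerSketch":
        """Read-set sketch; default scale 1 keeps every k-mer hash, so
        genome-sketch containment is exact with respect to the reads."""
        limit = _MASK64 // scale
        kept: set[int] = set()
        for read in reads:
            for kmer in _canonical_kmers(read, k):
                h = _hash64(kmer, seed)
                if h <= limit:
                    kept.add(h)
        return cls(k=k, scale=scale, seed=seed, hashes=frozenset(kept))

    def containment_in(self, other: "KmerSketch") -> float:
        if self.k != other.k or self.seed != other.seed:
            raise ValueError("incompatible sketches")
        if not self.hashes:
            return 0.0
        return len(self.hashes & other.hashes) / len(self.hashes)


def sketch_containment_ani(genome: str, read_set: Iterable[str],
                           k: int = 21, scale: int = 1000,
                           seed: int = 42,
                           read_sketch: Optional[KmerSketch] = None) -> float:
    """Estimated ANI (%) of a genome to a read sample from k-mer containment.

    C = fraction of the genome's sketched k-mers present among the read
    k-mers; ANI_est = 100 * C^(1/k) (a k-mer survives at identity p with
    probability ~p^k). Deterministic given the hash seed.
    """
    gsk = KmerSketch.from_sequence(genome, k=k, scale=scale, seed=seed)
    if read_sketch is None:
        read_sketch = KmerSketch.from_reads(read_set, k=k, seed=seed)
    c = gsk.containment_in(read_sketch)
    return 100.0 * c ** (1.0 / k) if c > 0 else 0.0


def fast_filter(genomes: Sequence[GenomeRecord], read_set: Sequence[str],
                ani_threshold_pct: float = 99.0, k: int = 21,
                scale: int = 1000, seed: int = 42) -> list[GenomeRecord]:
    """Retain genomes whose sketch ANI to the sample clears the threshold.

    Shrinks the genome set before graph construction; with an empty read
    set nothing can be retained (warned).
    """
    if not read_set:
        logger.warning("empty read set: fast filter retains nothing")
        return []
    read_sketch = KmerSketch.from_reads(read_set, k=k, seed=seed)
    kept = []
    for g in genomes:
        est = sketch_containment_ani(g.sequence, read_set, k=k, scale=scale,
                                     seed=seed, read_sketch=read_sketch)
        if est >= ani_threshold_pct:
            kept.append(g)
    return kept
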