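"""Species-level binning, false-positive filtering and abundance.

Each optimally-aligned read is assigned to the species whose graph its
alignment path lies in. Species supported by too few reads, or whose reads
are mostly low-confidence (low MAPQ), are flagged as false positives —
such signal typically arises from reads of a true species straying onto a
related species' shared genomic regions. For the retained set the
*normalized read coverage* c_i (total aligned read bases over mean strain
genome length) gives a mean-depth estimate, and relative abundances are
c_i renormalized over the retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align_model import GafRecord
from .graph_model import SuperGraph

__all__ = ["BinningConfig", "SpeciesBin", "SpeciesProfile", "bin_reads",
           "filter_species", "species_abundance", "write_species_profile"]

logger = logging.getLogger(__name__)


@dataclass
class BinningConfig:
    """Thresholds of the MAPQ-based species filter (all configurable)."""

    min_reads: int = 10            # minimum reads binned to a species
    mapq_cutoff: int = 30          # a read is high-confidence at mapq >= this
    min_highconf_frac: float = 0.25  # required fraction of high-confidence reads


@dataclass
class SpeciesBin:
    species_taxid: int
    read_ids: set[str] = field(default_factory=set)
    aligned_bases: int = 0
    n_highconf: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class SpeciesProfile:
    """Retained species with depth (c_i) and relative abundance."""

    retained: list[int]                    # taxids, deterministic order
    coverage: dict[int, float]             # taxid -> c_i (mean depth units)
    relative_abundance: dict[int, float]   # taxid -> share in [0,1]

    @property
    def is_empty(self) -> bool:
        return not self.retained


def bin_reads(supergraph: SuperGraph,
              best_alignments: dict[str, GafRecord],
              mapq_cutoff: int = 30) -> dict[int, SpeciesBin]:
    """Partition best-hit reads into per-species bins.

    The species of a record is the species of its first path step (the
    super-graph guarantees a path cannot straddle two species).
    """
    bins: dict[int, SpeciesBin] = {}
    for read_id, rec in best_alignments.items():
        try:
            taxid = supergraph.species_of_node(rec.path_steps[0][0])
        except KeyError:
            raise ValueError(
                f"read {read_id}: path step {rec.path_steps[0][0]} outside "
                f"every species id range") from None
        b = bins.setdefault(taxid, SpeciesBin(species_taxid=taxid))
        b.read_ids.add(read_id)
        b.aligned_bases += rec.read_end - rec.read_start
        if rec.effective_mapq >= mapq_cutoff:
            b.n_highconf += 1
    return bins


def filter_species(bins: dict[int, SpeciesBin],
                   config: BinningConfig = BinningConfig()) -> set[int]:
    """Retain species with enough reads and enough high-confidence reads.

    Species i is kept iff n_reads >= min_reads and
    n_highconf / n_reads >= min_highconf_frac.
    """
    retained = set()
    for taxid, b in bins.items():
        if b.n_reads < config.min_reads:
            continue
        if b.n_highconf / b.n_reads < config.min_highconf_frac:
            continue
        retained.add(taxid)
    return retained


def species_abundance(bins: dict[int, SpeciesBin], retained: set[int],
                      supergraph: SuperGraph) -> SpeciesProfile:
    """Normalized read coverage and relative abundance for retained species.

    c_i = aligned bases of species i / mean strain-genome length of its
    graph; relative abundance renormalizes c over the retained set.
    """
    if not retained:
        logger.warning("no species retained; empty species profile")
        return SpeciesProfile(retained=[], coverage={}, relative_abundance={})
    order = sorted(retained)
    cov = {}
    for taxid in order:
        mean_len = supergraph.graph_for(taxid).mean_genome_length_bp()
        cov[taxid] = bins[taxid].aligned_bases / mean_len
    total = sum(cov.values())
    rel = {t: (cov[t] / total if total > 0 else 0.0) for t in order}
    return SpeciesProfile(retained=order, coverage=cov, relative_abundance=rel)


def write_species_profile(profile: SpeciesProfile, dest) -> str:
    """Species profile as TSV: taxid, normalized coverage, relative abundance."""
    lines = ["species_taxid\tnormalized_read_coverage\trelative_abundance"]
    for taxid in profile.retained:
        lines.append(f"{taxid}\t{profile.coverage[taxid]:.6g}"
                     f"\t{profile.relative_abundance[taxid]:.6g}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
    return text
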