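"""Exon-based marker design for a targeted SNP panel.

Transcriptome contigs are mapped against a reference gene-model set
(Xenopus tropicalis exon structure); each contig then yields at most one
candidate exon, chosen to avoid untranslated regions:

* priority 1 — the exon matches more than twice within the gene model.
  With exactly three matches the central one is taken; with more, a seeded
  random choice among interior exons (never the first or last) keeps the
  candidate away from the model's extremes.
* priority 2 — the exon matches twice; the longer match is taken.
* priority 3 — a single match; kept but deprioritised, since a lone exon
  carries no positional information and may include noncoding sequence.

Candidates are then length-filtered (100-400 bp inclusive, long enough for
primer attachment yet within typical exon length) and ranked by BLAST hit
quality to a target panel size (default 192).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class ExonMatch:
    """One matched exon: index within the gene model, and its span."""

    exon_index: int
    length: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("exon length must be positive")


@dataclass(frozen=True)
class HitMetrics:
    percent_identity: float
    e_value: float
    gap_count: int
    multi_hit: bool = False
    duplicate_contig: bool = False


@dataclass
class ContigExonMap:
    """A contig's ordered exon matches against one gene model."""

    contig_id: str
    gene_model_id: str
    matched_exons: list[ExonMatch]
    hit_metrics: HitMetrics

    def __post_init__(self) -> None:
        idx = [e.exon_index for e in self.matched_exons]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"{self.contig_id}: exon indices must strictly increase")


@dataclass
class ExonSelection:
    contig_id: str
    gene_model_id: str
    exon_index: int
    length: int
    priority: int
    hit_metrics: HitMetrics = field(
        default_factory=lambda: HitMetrics(100.0, 0.0, 0))


def _contig_rng(contig_id: str, seed: int) -> np.random.Generator:
    """Per-contig RNG so the interior-exon draw is order-independent."""
    digest = hashlib.sha256(f"{seed}:{contig_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def assign_exon_priority(contig_map: ContigExonMap, seed: int = 0,
                         ) -> ExonSelection:
    """Pick one exon per contig and assign its priority class.

    >2 matches -> priority 1 (central exon for three matches, otherwise a
    seeded uniform choice among interior exons); 2 matches -> priority 2,
    longest exon; 1 match -> priority 3.
    """
    exons = contig_map.matched_exons
    if not exons:
        raise ValueError(f"{contig_map.contig_id}: no matched exons")
    if len(exons) == 1:
        chosen, priority = exons[0], 3
    elif len(exons) == 2:
        chosen = max(exons, key=lambda e: e.length)
        priority = 2
    elif len(exons) == 3:
        chosen, priority = exons[1], 1
    else:
        interior = exons[1:-1]
        rng = _contig_rng(contig_map.contig_id, seed)
        chosen = interior[rng.integers(len(interior))]
        priority = 1
    return ExonSelection(contig_map.contig_id, contig_map.gene_model_id,
                         chosen.exon_index, chosen.length, priority,
                         contig_map.hit_metrics)


def length_filter(selections: list[ExonSelection], min_len: int = 100,
                  max_len: int = 400) -> list[ExonSelection]:
    """Keep candidates whose exon length lies in [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [s for s in selections if min_len <= s.length <= max_len]


def rank_candidates(selections: list[ExonSelection], n_target: int = 192,
                    ) -> list[ExonSelection]:
    """Rank suitability for SNP identification and truncate to the panel size.

    Candidates flagged as multi-hit or duplicated across contigs are removed;
    the rest sort by (priority, e-value, -identity, gaps, contig id), the
    contig id acting as a deterministic final tie-break.
    """
    clean = [s for s in selections
             if not (s.hit_metrics.multi_hit or s.hit_metrics.duplicate_contig)]
    ranked = sorted(clean, key=lambda s: (
        s.priority, s.hit_metrics.e_value, -s.hit_metrics.percent_identity,
        s.hit_metrics.gap_count, s.contig_id))
    if len(ranked) < n_target:
        logger.warning("only %d clean candidates for a target panel of %d",
                       len(ranked), n_target)
    return ranked[:n_target]


def find_candidate_snps(aligned_seq_m: str, aligned_seq_p: str,
                        ) -> list[tuple[int, str, str]]:
    """Fixed-difference positions between two aligned exon sequences.

    Returns 1-based positions with the (M allele, P allele) pair; columns
    containing a gap or an ambiguous base in either sequence are skipped.
    """
    if len(aligned_seq_m) != len(aligned_seq_p):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_seq_m)} vs "
            f"{len(aligned_seq_p)}")
    snps = []
    for pos, (a, b) in enumerate(zip(aligned_seq_m.upper(),
                                     aligned_seq_p.upper()), start=1):
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS and a != b:
            snps.append((pos, a, b))
    return snps


# ---------------------------------------------------------------------------
# tabular interchange
# ---------------------------------------------------------------------------

def selections_to_frame(selections: list[ExonSelection]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": s.contig_id, "gene_model": s.gene_model_id,
        "exon_index": s.exon_index, "length": s.length,
        "priority": s.priority,
        "percent_identity": s.hit_metrics.percent_identity,
        "e_value": s.hit_metrics.e_value,
        "gap_count": s.hit_metrics.gap_count,
    } for s in selections])


def read_contig_map_tsv(path) -> list[ContigExonMap]:
    """Load contig->exon mapping rows.

    Expected columns: contig, gene_model, exon_index, length, start, end,
    percent_identity, e_value, gap_count, multi_hit, duplicate_contig;
    one row per matched exon, hit metrics repeated per contig.
    """
    df = pd.read_csv(path, sep="\t")
    maps = []
    for (contig, gene), grp in df.groupby(["contig", "gene_model"],
                                          sort=True):
        grp = grp.sort_values("exon_index")
        first = grp.iloc[0]
        maps.append(ContigExonMap(
            contig_id=str(contig), gene_model_id=str(gene),
            matched_exons=[ExonMatch(int(r.exon_index), int(r.length),
                                     int(r.start), int(r.end))
                           for r in grp.itertuples()],
            hit_metrics=HitMetrics(float(first.percent_identity),
                                   float(first.e_value),
                                   int(first.gap_count),
                                   bool(first.multi_hit),
                                   bool(first.duplicate_contig))))
    return maps
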