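"""Rule engine that classifies contigs into matrisome categories and
ECM-localization confidence tiers.

The classifier composes per-contig evidence — InterPro-style domain hits,
reciprocal BLAST homology to the human matrisome, signal-peptide /
transmembrane / GPI predictions — through a fixed sequence of deterministic
rules:

1. deduplicate overlapping domain annotations (keep lowest e-value),
2. tentative category = category with the most matrisome-defining domains,
3. veto by excluding domains (kinase, phosphatase, integrin, 7TM ...) with a
   carve-out for domains that are legitimate in planarian ECM proteins,
4. tentative category from the best BLAST hit to a categorized human protein,
5. reconcile domain vs BLAST category (domain architecture wins, conflicts
   flagged for curation),
6. remove contigs with transmembrane segments, not counting a segment that is
   plausibly the signal peptide, and keeping known TM-bearing ECM families
   (collagens, MMPs),
7. a predicted C-terminal GPI anchor forces the ECM-affiliated category,
8. assign high/low ECM-localization confidence by an ordered rule list.

Every decision is recorded on the :class:`~planmat.types.MatrisomeCall` via
``provenance``, ``flags`` and ``exclusion_reason`` so a curator can audit the
call chain.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import (
    CATEGORIES,
    BlastHit,
    DomainCatalog,
    DomainHit,
    HumanMatrisomeMap,
    MatrisomeCall,
    ProteinRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class AnnotationConfig:
    """Evidence thresholds and rule parameters, defaults as used in practice."""

    domain_evalue_max: float = 0.1     # per-hit InterPro e-value cut
    blast_evalue_max: float = 0.01     # best-BLAST-hit e-value cut
    sp_window: int = 35                # fallback SP-like window (aa) when no cleavage site
    small_secreted_max_len: int = 200  # rule-4 size cut for weak secreted factors
    min_orf_aa: int = 30
    #: contig families routed to LOW confidence because they canonically act
    #: inside the secretory pathway (e.g. lysosomal cathepsins); matched
    #: against ProteinRecord.orf_group_id prefixes or explicit contig ids
    intracellular_pathway_contigs: frozenset[str] = frozenset()
    #: optional curator allow-list: contigs forced HIGH despite a
    #: non-matrisome plasma-membrane best hit (empty by default)
    high_confidence_allowlist: frozenset[str] = frozenset()


def deduplicate_domains(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Reduce a contig's domain hits to non-overlapping annotations.

    Greedy selection in ascending e-value order (ties: longer interval, then
    lexicographic domain accession); a hit is kept iff it overlaps no
    previously kept hit. Output is sorted by start position.
    """
    if not hits:
        return []
    contigs = {h.contig_id for h in hits}
    if len(contigs) > 1:
        raise ValueError(f"hits span multiple contigs: {sorted(contigs)}")
    ordered = sorted(hits, key=lambda h: (h.evalue, -(h.end - h.start), h.domain_id))
    kept: list[DomainHit] = []
    for h in ordered:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end))


def categorize_by_domains(
    hits: Sequence[DomainHit], catalog: DomainCatalog
) -> tuple[Optional[str], bool]:
    """Tentative category = argmax of defining-domain counts per category.

    Ties resolve by the fixed priority core > affiliated > regulator >
    secreted and set the tie flag. Returns ``(None, False)`` when no defining
    domain is present. Unknown accessions are ignored with a debug log.
    """
    counts: dict[str, int] = defaultdict(int)
    for h in hits:
        cat = catalog.defining.get(h.domain_id)
        if cat is not None:
            counts[cat] += 1
        elif h.domain_id not in catalog.excluding:
            logger.debug("domain %s not in catalog; ignored", h.domain_id)
    if not counts:
        return None, False
    best = max(counts.values())
    winners = [c for c in CATEGORIES if counts.get(c, 0) == best]
    return winners[0], len(winners) > 1


def apply_exclusions(
    category: str, hits: Sequence[DomainHit], catalog: DomainCatalog
) -> tuple[Optional[str], Optional[str]]:
    """Veto a tentative category if any hit carries an excluding domain.

    Exception-list domains never veto (the catalog drops them at load time).
    Returns ``(category, None)`` if retained, ``(None, reason)`` if excluded.
    """
    for h in hits:
        if catalog.excludes(h.domain_id, category):
            reason = f"excluding domain {h.domain_id} ({h.description}) for {category}"
            return None, reason
    return category, None


def _best_hit(hits: Iterable[BlastHit]) -> Optional[BlastHit]:
    hits = list(hits)
    if not hits:
        return None
    # lower e-value wins; ties: higher bitscore, then blastx over tblastn
    return min(
        hits, key=lambda h: (h.evalue, -h.bitscore, 0 if h.direction == "blastx" else 1)
    )


def categorize_by_blast(
    hits: Sequence[BlastHit],
    human_map: HumanMatrisomeMap,
    evalue_max: float = 0.01,
) -> Optional[str]:
    """Category of the best BLAST hit when it passes the e-value cut and maps
    to a categorized human matrisome protein; otherwise ``None``."""
    best = _best_hit(hits)
    if best is None or best.evalue >= evalue_max:
        return None
    cat = human_map.category_of(best.subject_id)
    if cat is None and best.subject_id not in human_map:
        logger.debug("blast subject %s absent from human matrisome map", best.subject_id)
    return cat


def reciprocal_best_hits(
    forward: Sequence[BlastHit], reverse: Sequence[BlastHit]
) -> set[tuple[str, str]]:
    """Mutual-best-hit (contig, human protein) pairs across both directions."""
    fwd_best: dict[str, BlastHit] = {}
    for q, hs in _group_by(forward, lambda h: h.query_id).items():
        fwd_best[q] = _best_hit(hs)
    rev_best: dict[str, BlastHit] = {}
    for q, hs in _group_by(reverse, lambda h: h.query_id).items():
        rev_best[q] = _best_hit(hs)
    pairs = set()
    for contig, hit in fwd_best.items():
        back = rev_best.get(hit.subject_id)
        if back is not None and back.subject_id == contig:
            pairs.add((contig, hit.subject_id))
    return pairs


def _group_by(items, key):
    out = defaultdict(list)
    for it in items:
        out[key(it)].append(it)
    return out


def reconcile_categories(
    domain_cat: Optional[str], blast_cat: Optional[str]
) -> tuple[str, bool]:
    """Merge the two tentative categories; domain architecture wins conflicts.

    Returns ``(category, conflict_flag)``; raises if both are absent.
    """
    if domain_cat is None and blast_cat is None:
        raise ValueError("not a matrisome candidate: no domain or blast category")
    if domain_cat is None:
        return blast_cat, False  # type: ignore[return-value]
    if blast_cat is None or blast_cat == domain_cat:
        return domain_cat, False
    return domain_cat, True


def filter_transmembrane(
    record: ProteinRecord,
    call: MatrisomeCall,
    catalog: DomainCatalog,
    hits: Sequence[DomainHit] = (),
    sp_window: int = 35,
) -> MatrisomeCall:
    """Exclude calls on proteins with a genuine transmembrane segment.

    A TM segment is discounted as signal-peptide-like when the protein has a
    predicted signal peptide and the segment starts at or before the predicted
    cleavage position (or within ``sp_window`` aa when no cleavage position is
    available). Contigs carrying a keep-list domain family (collagen triple
    helix, MMP catalytic domain) are retained with the ``keep_list`` flag.
    """
    if not call.retained and call.category is None:
        return call
    window = record.sp_cleavage_pos if (
        record.signal_peptide and record.sp_cleavage_pos is not None
    ) else sp_window
    genuine_tm = [
        seg for seg in record.tm_segments
        if not (record.signal_peptide and seg[0] <= window)
    ]
    if not genuine_tm:
        return call
    if any(h.domain_id in catalog.keep_list_domains for h in hits):
        call.flags.add("keep_list")
        return call
    call.exclude(
        f"transmembrane segment at {genuine_tm[0][0]}-{genuine_tm[0][1]}",
        flag="tm_removed",
    )
    return call


def assign_gpi(record: ProteinRecord, call: MatrisomeCall) -> MatrisomeCall:
    """A predicted C-terminal GPI anchor forces the ECM-affiliated category."""
    if call.category is None:  # exclusion is terminal
        return call
    if record.gpi_anchor:
        call.category = "affiliated"
        call.provenance.add("gpi")
    return call


def assign_confidence(
    record: ProteinRecord,
    call: MatrisomeCall,
    has_defining_domain: bool,
    rbh_human_matrisome: bool,
    config: AnnotationConfig,
) -> MatrisomeCall:
    """ECM-localization confidence by ordered rules; first match wins.

    1. HIGH — signal peptide and at least one matrisome-defining domain.
    2. HIGH — reciprocal best hit to a human matrisome protein plus a
       defining domain (clear homologous domain organization).
    3. LOW — defining domain but no called signal peptide.
    4. LOW — signal peptide, no defining domain, short protein (<200 aa):
       weakly characterized small secreted factors.
    5. LOW — family on the configured intracellular-secretory-pathway list
       (e.g. lysosomal cathepsins).
    6. LOW — everything else retained.

    An optional curator allow-list promotes specific contigs to HIGH ahead of
    the rules. The matched rule id is recorded in ``flags``.
    """
    if call.category is None:
        return call
    if record.contig_id in config.high_confidence_allowlist:
        call.confidence = "high"
        call.flags.add("confidence_rule:allowlist")
        return call
    if record.contig_id in config.intracellular_pathway_contigs or (
        record.orf_group_id is not None
        and record.orf_group_id in config.intracellular_pathway_contigs
    ):
        call.confidence = "low"
        call.flags.add("confidence_rule:5")
        return call
    if record.signal_peptide and has_defining_domain:
        call.confidence, rule = "high", "1"
    elif rbh_human_matrisome and has_defining_domain:
        call.confidence, rule = "high", "2"
    elif has_defining_domain and not record.signal_peptide:
        call.confidence, rule = "low", "3"
    elif (
        record.signal_peptide
        and not has_defining_domain
        and record.protein_length < config.small_secreted_max_len
    ):
        call.confidence, rule = "low", "4"
    else:
        call.confidence, rule = "low", "6"
    call.flags.add(f"confidence_rule:{rule}")
    return call


def representative_contig(group: Sequence[ProteinRecord]) -> tuple[str, bool]:
    """Pick the representative contig of a multi-contig gene: largest average
    read count in the single-cell data; ties go to the lexicographically
    smallest id and are flagged."""
    if not group:
        raise ValueError("empty contig group")
    best = min(group, key=lambda r: (-r.avg_read_count, r.contig_id))
    tie = sum(1 for r in group if r.avg_read_count == best.avg_read_count) > 1
    return best.contig_id, tie


@dataclass
class EvidenceBundle:
    """All per-contig evidence tables consumed by :func:`annotate_matrisome`."""

    domain_hits: dict[str, list[DomainHit]] = field(default_factory=dict)
    blast_forward: dict[str, list[BlastHit]] = field(default_factory=dict)
    blast_reverse: list[BlastHit] = field(default_factory=list)
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def validate(self) -> None:
        for name, table in [
            ("domain_hits", self.domain_hits),
            ("records", self.records),
        ]:
            if table is None:
                raise ValueError(f"missing evidence table: {name}")


def annotate_matrisome(
    bundle: EvidenceBundle,
    catalog: DomainCatalog,
    human_map: HumanMatrisomeMap,
    config: Optional[AnnotationConfig] = None,
) -> list[MatrisomeCall]:
    """Run the full classification chain over every candidate contig.

    The candidate universe is the union of contigs with at least one defining
    domain and contigs whose best BLAST hit maps to a human matrisome
    category; everything else in the bundle is reported as excluded with
    reason ``no matrisome evidence``. Deterministic given inputs and config;
    independent of input row order.
    """
    config = config or AnnotationConfig()
    bundle.validate()

    all_fwd = [h for hs in bundle.blast_forward.values() for h in hs]
    rbh = reciprocal_best_hits(all_fwd, bundle.blast_reverse)
    rbh_matrisome_contigs = {
        c for c, s in rbh if human_map.category_of(s) is not None
    }

    contigs = sorted(
        set(bundle.domain_hits) | set(bundle.blast_forward) | set(bundle.records)
    )
    calls: list[MatrisomeCall] = []
    for contig in contigs:
        raw_hits = [
            h for h in bundle.domain_hits.get(contig, [])
            if h.evalue < config.domain_evalue_max
        ]
        hits = deduplicate_domains(raw_hits)
        domain_cat, tie = categorize_by_domains(hits, catalog)
        call = MatrisomeCall(contig_id=contig)
        if tie:
            call.flags.add("tie_broken")

        excl_reason = None
        if domain_cat is not None:
            domain_cat, excl_reason = apply_exclusions(domain_cat, hits, catalog)

        blast_cat = categorize_by_blast(
            bundle.blast_forward.get(contig, []), human_map, config.blast_evalue_max
        )

        if domain_cat is None and blast_cat is None:
            if excl_reason is not None:
                call.exclude(excl_reason, flag="excluding_domain")
            else:
                call.exclude("no matrisome evidence")
            calls.append(call)
            continue
        if excl_reason is not None:
            # domain category vetoed; excluding-domain veto is terminal even
            # when a blast category exists (the domain content contradicts
            # ECM localization)
            call.exclude(excl_reason, flag="excluding_domain")
            calls.append(call)
            continue

        category, conflict = reconcile_categories(domain_cat, blast_cat)
        call.category = category
        if domain_cat is not None:
            call.provenance.add("domain")
        if blast_cat is not None:
            call.provenance.add("blast")
        if conflict:
            call.flags.add("category_conflict")

        record = bundle.records.get(contig)
        if record is None:
            record = ProteinRecord(contig_id=contig, protein_length=1)
        call = filter_transmembrane(
            record, call, catalog, hits, sp_window=config.sp_window
        )
        call = assign_gpi(record, call)
        if call.category is not None:
            has_def = any(catalog.is_defining(h.domain_id) for h in hits)
            call = assign_confidence(
                record,
                call,
                has_defining_domain=has_def,
                rbh_human_matrisome=contig in rbh_matrisome_contigs,
                config=config,
            )
        call.validate()
        calls.append(call)
    return calls
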