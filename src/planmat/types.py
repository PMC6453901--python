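"""Core data containers shared across the annotation and expression modules.

Coordinates on protein sequences are 1-based inclusive amino-acid positions,
the convention used by InterProScan and the topology predictors whose outputs
these containers hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

#: The four matrisome categories, in tie-break priority order. The core
#: matrisome (collagens, glycoproteins, proteoglycans) is the most highly
#: curated tier and wins ties.
CATEGORIES: tuple[str, ...] = ("core", "affiliated", "regulator", "secreted")

#: Domains that are never treated as excluding for any category in planarians:
#: C1q, animal haem peroxidase, TIL, fringe, C345C (NTR) and Kazal. Each of
#: these would veto a genuine planarian ECM protein (e.g. the TIL domain of a
#: mucin-like core glycoprotein), so they are carved out of the exclusion
#: dictionary and instead count as evidence for categorization.
DEFAULT_EXCEPTION_DOMAINS: frozenset[str] = frozenset(
    {"IPR001073", "IPR002007", "IPR002919", "IPR020067", "IPR018933", "IPR002350"}
)


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain annotation on a contig's predicted protein."""

    contig_id: str
    domain_id: str
    description: str
    evalue: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.domain_id}: {self.evalue}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad interval [{self.start}, {self.end}] for {self.domain_id}"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class DomainCatalog:
    """Matrisome-defining / excluding domain dictionary.

    ``defining`` maps a domain accession to the category whose membership it
    predicts; ``excluding`` maps an accession to the set of categories it
    vetoes. Accessions in ``exceptions`` are removed from ``excluding`` on
    construction and never veto anything.
    """

    defining: dict[str, str]
    excluding: dict[str, set[str]]
    exceptions: frozenset[str] = DEFAULT_EXCEPTION_DOMAINS
    #: domain families whose presence puts a contig on the transmembrane
    #: keep list (known TM-bearing ECM components: collagens, MMPs)
    keep_list_domains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for cat in self.defining.values():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} in defining map")
        # exception domains never exclude
        self.excluding = {
            d: set(cats) for d, cats in self.excluding.items() if d not in self.exceptions
        }

    def is_defining(self, domain_id: str) -> bool:
        return domain_id in self.defining

    def excludes(self, domain_id: str, category: str) -> bool:
        return category in self.excluding.get(domain_id, ())


@dataclass(frozen=True)
class BlastHit:
    """Directional homology hit between a contig and a human protein."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    direction: str  # "blastx" (contig protein vs human) or "tblastn"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")
        if self.direction not in ("blastx", "tblastn"):
            raise ValueError(f"unknown direction {self.direction!r}")


class HumanMatrisomeMap(dict):
    """subject_id -> category; ``non_matrisome`` entries mark known negatives.

    Values may carry an annotation suffix after ':' (e.g.
    ``non_matrisome:plasma-membrane``); :meth:`category_of` strips it.
    """

    def category_of(self, subject_id: str) -> Optional[str]:
        raw = self.get(subject_id)
        if raw is None:
            return None
        base = raw.split(":", 1)[0]
        return base if base in CATEGORIES else None


@dataclass
class ProteinRecord:
    """Sequence-level evidence for one contig's predicted protein."""

    contig_id: str
    protein_length: int
    signal_peptide: bool = False
    sp_cleavage_pos: Optional[int] = None
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    gpi_anchor: bool = False
    avg_read_count: float = 0.0
    orf_group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sp_cleavage_pos is not None and not self.signal_peptide:
            raise ValueError("sp_cleavage_pos given without signal_peptide")
        for s, e in self.tm_segments:
            if not (1 <= s <= e <= self.protein_length):
                raise ValueError(
                    f"TM segment [{s},{e}] outside protein of length "
                    f"{self.protein_length} ({self.contig_id})"
                )


@dataclass
class MatrisomeCall:
    """Final classification of one contig.

    ``confidence`` is ``high``/``low`` for retained ECM-localized calls and
    ``excluded`` otherwise; exclusion is terminal, so an excluded call never
    carries a category.
    """

    contig_id: str
    category: Optional[str] = None
    confidence: str = "excluded"
    provenance: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)
    exclusion_reason: Optional[str] = None

    def validate(self) -> None:
        if (self.confidence == "excluded") != (self.category is None):
            raise ValueError(
                f"{self.contig_id}: confidence={self.confidence} inconsistent "
                f"with category={self.category}"
            )
        if self.category is not None and not self.provenance:
            raise ValueError(f"{self.contig_id}: categorized call lacks provenance")

    def exclude(self, reason: str, flag: Optional[str] = None) -> None:
        self.category = None
        self.confidence = "excluded"
        self.exclusion_reason = reason
        if flag:
            self.flags.add(flag)

    @property
    def retained(self) -> bool:
        return self.confidence in ("high", "low")


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells UMI count matrix with optional normalized layer."""

    counts: sparse.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    norm: Optional[np.ndarray] = None
    state: str = "raw"  # raw | cp10k | log_cp10k

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids if g in lookup], dtype=int)


@dataclass
class CellAnnotation:
    """Per-cell type labels (e.g. the nine broad planarian tissue classes)."""

    cell_ids: list[str]
    type_labels: list[str]
    cluster_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.type_labels):
            raise ValueError("cell_ids and type_labels differ in length")

    def labels_for(self, cell_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.cell_ids, self.type_labels))
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValueError(f"{len(missing)} cells lack a type label, e.g. {missing[0]}")
        return np.array([lookup[c] for c in cell_ids])


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def intersect(self, gene_ids) -> "GeneSet":
        return GeneSet(self.name, self.members & set(gene_ids))


def to_dataframe(calls: list[MatrisomeCall]) -> pd.DataFrame:
    """Tabular view of annotation calls (one row per contig)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "contig_id": c.contig_id,
                "category": c.category or "",
                "confidence": c.confidence,
                "provenance": ",".join(sorted(c.provenance)),
                "flags": ",".join(sorted(c.flags)),
                "exclusion_reason": c.exclusion_reason or "",
            }
        )
    return pd.DataFrame(rows, columns=[
        "contig_id", "category", "confidence", "provenance", "flags",
        "exclusion_reason",
    ])
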