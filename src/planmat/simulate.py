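"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`gen_evidence_bundle` emits annotation evidence tables (domain hits,
  bidirectional BLAST, signal-peptide / TM / GPI predictions) for contigs of
  known true matrisome category or decoy class, exercising every branch of
  the classifier: the excluding-domain veto and its exception carve-out, the
  transmembrane filter and its collagen/MMP keep list, GPI-driven
  re-categorization, the confidence rules, and domain-vs-BLAST conflicts.

* :func:`gen_sc_counts` draws a negative-binomial UMI count matrix over K
  cell types in which one type ("muscle", ~10% of cells by default)
  coherently over-expresses a designated core-matrisome gene program — the
  statistical structure that module scoring, specificity AUC and
  matrisome-restricted reclustering are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .annotate import EvidenceBundle
from .types import (
    BlastHit,
    CellAnnotation,
    DomainCatalog,
    DomainHit,
    ExpressionMatrix,
    GeneSet,
    ProteinRecord,
)

# domain accessions drawn from the packaged catalog
_CORE_DOMAINS = ["IPR008160", "IPR000885", "IPR002035", "IPR001846", "IPR001007"]
_AFFIL_DOMAINS = ["IPR001304", "IPR001079", "IPR000922"]
_REG_DOMAINS = ["IPR000215", "IPR001134", "IPR000010"]
_SEC_DOMAINS = ["IPR005817", "IPR001839", "IPR002209"]
_KINASE = "IPR000719"
_TIL = "IPR002919"
_COLLAGEN_TRIPLE_HELIX = "IPR008160"
_DESC = "synthetic domain"

#: evidence classes and the call each must force under the default config
EVIDENCE_CLASSES = {
    "core_sp": ("core", "high"),
    "core_no_sp": ("core", "low"),
    "affiliated_gpi": ("affiliated", "high"),
    "regulator": ("regulator", "high"),
    "secreted": ("secreted", "high"),
    "mucin_til": ("core", "high"),        # TIL would veto core but is excepted
    "collagen_tm": ("core", "high"),      # TM segment survives via keep list
    "small_secreted": ("secreted", "low"),
    "kinase_decoy": (None, "excluded"),
    "tm_receptor_decoy": (None, "excluded"),
    "intracellular_decoy": (None, "excluded"),
    "conflict": ("regulator", "high"),    # domain regulator vs blast core
}


@dataclass
class EvidenceTruth:
    """Per-contig ground truth for a generated evidence bundle."""

    table: pd.DataFrame  # contig_id, class, true_category, true_confidence

    def of_class(self, cls: str) -> list[str]:
        return list(self.table.loc[self.table["class"] == cls, "contig_id"])


def _domain_hits(contig, domains, rng, start=40):
    hits, pos = [], start
    for d in domains:
        length = int(rng.integers(40, 90))
        hits.append(
            DomainHit(
                contig_id=contig,
                domain_id=d,
                description=_DESC,
                evalue=float(10.0 ** rng.uniform(-20, -4)),
                start=pos,
                end=pos + length,
            )
        )
        pos += length + int(rng.integers(5, 20))
    return hits


def gen_evidence_bundle(
    n_per_class: dict[str, int] | int = 20, seed: int = 1
) -> tuple[EvidenceBundle, dict[str, str], EvidenceTruth]:
    """Generate an evidence bundle plus the human matrisome map and truth.

    ``n_per_class`` is either a uniform count or a map class -> count over
    :data:`EVIDENCE_CLASSES`. Returns ``(bundle, human_map, truth)`` where
    ``human_map`` maps synthetic human accessions to categories.
    """
    if isinstance(n_per_class, int):
        n_per_class = {cls: n_per_class for cls in EVIDENCE_CLASSES}
    unknown = set(n_per_class) - set(EVIDENCE_CLASSES)
    if unknown:
        raise ValueError(f"unknown evidence classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    bundle = EvidenceBundle()
    human_map: dict[str, str] = {}
    truth_rows = []
    serial = 0

    cat_domains = {
        "core": _CORE_DOMAINS,
        "affiliated": _AFFIL_DOMAINS,
        "regulator": _REG_DOMAINS,
        "secreted": _SEC_DOMAINS,
    }

    for cls, n in sorted(n_per_class.items()):
        true_cat, true_conf = EVIDENCE_CLASSES[cls]
        for _ in range(n):
            serial += 1
            contig = f"dd_syn_{serial:04d}_{cls}"
            human = f"NP_SYN{serial:05d}"
            plen = int(rng.integers(250, 600))
            sp, cleave, tms, gpi = True, int(rng.integers(18, 30)), [], False
            domains: list[str] = []
            blast_cat = true_cat

            if cls == "core_sp":
                domains = list(rng.choice(_CORE_DOMAINS, 2, replace=False))
            elif cls == "core_no_sp":
                domains = list(rng.choice(_CORE_DOMAINS, 2, replace=False))
                sp, cleave = False, None
            elif cls == "affiliated_gpi":
                domains = [str(rng.choice(_AFFIL_DOMAINS))]
                gpi = True
            elif cls == "regulator":
                domains = list(rng.choice(_REG_DOMAINS, 2, replace=False))
            elif cls == "secreted":
                domains = [str(rng.choice(_SEC_DOMAINS))]
            elif cls == "mucin_til":
                # two core domains outvote the (excepted) TIL regulator domain
                domains = ["IPR001846", "IPR001007", _TIL]
            elif cls == "collagen_tm":
                domains = [_COLLAGEN_TRIPLE_HELIX, "IPR000885"]
                tms = [(int(rng.integers(200, plen - 40)),)]
                tms = [(tms[0][0], tms[0][0] + 22)]
            elif cls == "small_secreted":
                plen = int(rng.integers(80, 180))
                domains = []  # SP only; weak unidentified domains
                blast_cat = "secreted"
            elif cls == "kinase_decoy":
                domains = [str(rng.choice(_CORE_DOMAINS)), _KINASE]
                blast_cat = None
            elif cls == "tm_receptor_decoy":
                # surface receptor: lectin-like domain plus a genuine TM
                # segment, no keep-list family -> removed by the TM filter
                domains = [str(rng.choice(_AFFIL_DOMAINS))]
                sp, cleave = False, None
                start = int(rng.integers(120, plen - 40))
                tms = [(start, start + 22)]
                blast_cat = None
            elif cls == "intracellular_decoy":
                domains = []
                sp, cleave = False, None
                blast_cat = None  # best hit to a non-matrisome human protein
            elif cls == "conflict":
                domains = list(rng.choice(_REG_DOMAINS, 2, replace=False))
                blast_cat = "core"

            if domains:
                bundle.domain_hits[contig] = _domain_hits(contig, domains, rng)
            bundle.records[contig] = ProteinRecord(
                contig_id=contig,
                protein_length=plen,
                signal_peptide=sp,
                sp_cleavage_pos=cleave,
                tm_segments=[(s, min(e, plen)) for s, e in tms],
                gpi_anchor=gpi,
                avg_read_count=float(rng.gamma(2.0, 2.0)),
            )

            # forward blast hit; decoy classes hit non-matrisome proteins
            ev = float(10.0 ** rng.uniform(-40, -6))
            bits = float(rng.uniform(80, 400))
            if cls == "intracellular_decoy":
                human_map[human] = "non_matrisome:cytoplasmic"
            elif cls == "tm_receptor_decoy":
                human_map[human] = "non_matrisome:plasma-membrane"
            elif cls == "kinase_decoy":
                human_map[human] = "non_matrisome:kinase"
            else:
                human_map[human] = blast_cat if blast_cat else "non_matrisome"
            bundle.blast_forward[contig] = [
                BlastHit(contig, human, ev, bits, "blastx")
            ]
            # mutually consistent reverse hit => reciprocal best pair; the
            # no-signal-peptide class is deliberately not reciprocal so its
            # confidence rests on domain evidence alone
            if cls != "core_no_sp":
                bundle.blast_reverse.append(
                    BlastHit(human, contig, ev, bits, "tblastn")
                )

            truth_rows.append(
                {
                    "contig_id": contig,
                    "class": cls,
                    "true_category": true_cat or "",
                    "true_confidence": true_conf,
                }
            )

    truth = EvidenceTruth(pd.DataFrame(truth_rows))
    return bundle, human_map, truth


@dataclass
class SimConfig:
    """Parameters of the single-cell count simulation.

    Defaults emulate a whole-animal atlas in which muscle is one distinct
    cell type holding ~10% of cells and coherently over-expresses a
    50-gene core-matrisome program at fold-change 8.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    cell_types: dict[str, float] = field(
        default_factory=lambda: {
            "muscle": 0.10,
            "neural": 0.18,
            "epidermis": 0.16,
            "intestine": 0.12,
            "neoblast": 0.16,
            "parenchymal": 0.08,
            "protonephridia": 0.06,
            "cathepsin": 0.08,
            "pharynx": 0.06,
        }
    )
    lib_mu: float = 8.5        # log-normal library size, ln-scale mean (~5k UMIs)
    lib_sigma: float = 0.35
    gene_mean_shape: float = 0.6   # gamma baseline of relative gene expression
    gene_mean_scale: float = 1.0
    dispersion: float = 0.3        # NB: var = mu + dispersion * mu^2
    matrisome_set_size: int = 50
    matrisome_fc: float = 8.0      # fold-change of the matrisome set in muscle
    marker_genes_per_type: int = 20
    marker_fc: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.cell_types.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")
        if self.matrisome_fc < 1 or self.marker_fc < 1:
            raise ValueError("fold-changes must be >= 1")
        for name in ("lib_mu", "lib_sigma", "gene_mean_shape", "gene_mean_scale",
                     "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        need = self.matrisome_set_size + self.marker_genes_per_type * len(self.cell_types)
        if need > self.n_genes:
            raise ValueError("not enough genes for the requested programs")


def gen_sc_counts(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, dict[str, GeneSet]]:
    """Draw a negative-binomial genes x cells UMI matrix with planted programs.

    Expected counts for gene g in cell c are ``lib_c * f_gc * base_g /
    sum_g'(f_g'c * base_g')`` so per-cell totals track the drawn library
    sizes; ``f_gc`` is the matrisome fold-change for matrisome genes in
    muscle cells and the marker fold-change for each type's marker genes.
    Counts are gamma-Poisson with shared dispersion. Returns the matrix, the
    true cell-type annotation, and the planted gene sets (key ``matrisome``
    plus ``markers_<type>``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.cell_types)
    probs = np.array([cfg.cell_types[t] for t in types])
    labels = rng.choice(types, size=cfg.n_cells, p=probs)

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    base = rng.gamma(cfg.gene_mean_shape, cfg.gene_mean_scale, size=cfg.n_genes)
    base = np.maximum(base, 1e-4)

    # disjoint planted programs
    perm = rng.permutation(cfg.n_genes)
    cursor = 0
    mat_idx = perm[cursor : cursor + cfg.matrisome_set_size]
    cursor += cfg.matrisome_set_size
    marker_idx: dict[str, np.ndarray] = {}
    for t in types:
        marker_idx[t] = perm[cursor : cursor + cfg.marker_genes_per_type]
        cursor += cfg.marker_genes_per_type

    # per-type fold-change matrix (types x genes)
    fc = np.ones((len(types), cfg.n_genes))
    for k, t in enumerate(types):
        fc[k, marker_idx[t]] = cfg.marker_fc
        if t == "muscle":
            fc[k, mat_idx] = cfg.matrisome_fc

    lib = rng.lognormal(cfg.lib_mu, cfg.lib_sigma, size=cfg.n_cells)
    type_of = np.array([types.index(t) for t in labels])
    # global relative baseline: planted fold-changes multiply gene means
    # directly, so the empirical muscle/other mean ratio of a matrisome gene
    # is f (cells of the over-expressing type end up with slightly larger
    # libraries, as secretory cell types do)
    rel = base / base.sum()
    mu = lib[:, None] * rel[None, :] * fc[type_of, :]   # cells x genes
    r = 1.0 / cfg.dispersion                     # NB size parameter
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = ExpressionMatrix(
        counts=sparse.csr_matrix(counts.T),      # genes x cells
        gene_ids=gene_ids,
        cell_ids=[f"cell{i:05d}" for i in range(cfg.n_cells)],
    )
    annot = CellAnnotation(cell_ids=list(matrix.cell_ids), type_labels=list(labels))
    sets = {
        "matrisome": GeneSet(
            "matrisome", frozenset(gene_ids[i] for i in mat_idx)
        )
    }
    for t in types:
        sets[f"markers_{t}"] = GeneSet(
            f"markers_{t}", frozenset(gene_ids[i] for i in marker_idx[t])
        )
    return matrix, annot, sets
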