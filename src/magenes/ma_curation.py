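"""Decision procedure assigning candidates to the seven MA gene types.

The pipeline mirrors the curation workflow used to build a methylated-amine
gene database: a >60-bit homology screen against experimentally validated
seeds, clade placement against reference sequences, then a per-type rule —
active-residue confirmation for the TMA-producing types (cutC, cntA/yeaW,
grdI) and the methylamine methyltransferases (mtmB, mtbB), or the
MTTB-superfamily split for mttB/mtxB, where the presence of pyrrolysine at
the anchor's Pyl column distinguishes the TMA-specific MttB from the
non-Pyl MtxB.  Truncated MTTB hits are re-called from their scaffold with
amber read-through before the split is applied.

Genomes are then classified by their curated gene inventory as
proatherogenic (TMA-producing), non-TMA producing, both, or none.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from . import homology, orf_amber
from .homology import DEFAULT_PARAMS, ResidueProfile, ScoringParams
from .seq_io import GENE_TYPES, NON_TMA, PROATHEROGENIC, SeqRecord, gene_role

#: Minimum protein length (aa) above which a pyrrolysine-free MTTB hit that
#: aligns through the Pyl column is accepted as MtxB; hits at or below it
#: are treated as potentially truncated Pyl genes.
MTTB_MIN_LEN_AA = 360


@dataclass
class GeneTypeConfig:
    """Everything needed to curate one gene type."""

    gene_type: str
    seeds: list[SeqRecord]
    profile: Optional[ResidueProfile] = None  # residue-check types
    references_positive: list[SeqRecord] = field(default_factory=list)
    references_negative: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError(f"gene type {self.gene_type!r}: no seeds configured")


@dataclass
class CurationConfig:
    types: dict[str, GeneTypeConfig]
    params: ScoringParams = DEFAULT_PARAMS
    min_bits: float = 60.0
    mttb_min_len_aa: int = MTTB_MIN_LEN_AA
    min_anchor_fraction: float = 0.8

    def for_type(self, gene_type: str) -> GeneTypeConfig:
        try:
            return self.types[gene_type]
        except KeyError:
            raise KeyError(f"no curation config for gene type {gene_type!r}") from None


@dataclass
class GeneAssignment:
    candidate_id: str
    gene_type: Optional[str]
    bitscore: float = 0.0
    clade_pass: Optional[bool] = None
    residues_pass: Optional[bool] = None
    length_aa: int = 0
    pyl_column_residue: Optional[str] = None
    n_amber_readthrough: int = 0
    reject_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_type == "mttB":
            assert self.n_amber_readthrough >= 1 and self.pyl_column_residue == "O"
        if self.gene_type == "mtxB":
            assert self.n_amber_readthrough == 0

    @property
    def accepted(self) -> bool:
        return self.gene_type is not None

    @property
    def role(self) -> Optional[str]:
        return gene_role(self.gene_type) if self.gene_type else None


def classify_mttb_superfamily(
    candidate: SeqRecord,
    anchor: SeqRecord,
    pyl_column: int,
    nt_context: Optional[tuple[SeqRecord, tuple[int, int], str]] = None,
    min_len_aa: int = MTTB_MIN_LEN_AA,
    min_anchor_fraction: float = 0.8,
    params: ScoringParams = DEFAULT_PARAMS,
    bitscore: float = 0.0,
) -> GeneAssignment:
    """Split a screened MTTB-superfamily hit into mttB / mtxB / reject.

    Rules, in order: a candidate longer than ``min_len_aa`` with no
    pyrrolysine whose alignment covers the anchor's Pyl column with a
    standard residue is MtxB.  A candidate carrying 'O' that maps onto the
    Pyl column is MttB; if the hit is TAG-truncated, ``nt_context``
    (scaffold, forward-strand region, strand) lets the amber read-through
    recaller recover the full protein first.  A short Pyl-free hit with no
    nucleotide context cannot be resolved and is rejected.
    """
    if not (0 <= pyl_column < len(anchor)):
        raise ValueError(f"pyl_column {pyl_column} outside anchor (len {len(anchor)})")
    seq = candidate.upper
    n_amber = 0
    # try read-through recall when the protein is short and Pyl-free
    if "O" not in seq and len(seq) <= min_len_aa:
        if nt_context is None:
            return GeneAssignment(
                candidate_id=candidate.id,
                gene_type=None,
                bitscore=bitscore,
                length_aa=len(seq),
                reject_reasons=["truncated_no_context"],
            )
        scaffold, region, strand = nt_context
        call = orf_amber.recall_truncated(
            scaffold,
            region,
            strand,
            anchor,
            min_anchor_fraction=min_anchor_fraction,
        )
        if call is None:
            return GeneAssignment(
                candidate_id=candidate.id,
                gene_type=None,
                bitscore=bitscore,
                length_aa=len(seq),
                reject_reasons=["readthrough_recall_failed"],
            )
        seq = call.protein
        n_amber = call.n_readthrough
    elif "O" in seq:
        n_amber = seq.count("O")

    mapping = homology.map_to_anchor(seq, anchor, params)
    pyl_pos = mapping[pyl_column]
    pyl_res = seq[pyl_pos] if pyl_pos is not None else None

    if "O" in seq:
        if pyl_res == "O":
            return GeneAssignment(
                candidate_id=candidate.id,
                gene_type="mttB",
                bitscore=bitscore,
                length_aa=len(seq),
                pyl_column_residue="O",
                n_amber_readthrough=n_amber,
            )
        return GeneAssignment(
            candidate_id=candidate.id,
            gene_type=None,
            bitscore=bitscore,
            length_aa=len(seq),
            pyl_column_residue=pyl_res,
            n_amber_readthrough=n_amber,
            reject_reasons=["amber_off_column"],
        )
    if len(seq) > min_len_aa and pyl_res is not None:
        return GeneAssignment(
            candidate_id=candidate.id,
            gene_type="mtxB",
            bitscore=bitscore,
            length_aa=len(seq),
            pyl_column_residue=pyl_res,
            n_amber_readthrough=0,
        )
    reason = "pyl_column_unaligned" if pyl_res is None else "length_filter"
    return GeneAssignment(
        candidate_id=candidate.id,
        gene_type=None,
        bitscore=bitscore,
        length_aa=len(seq),
        pyl_column_residue=pyl_res,
        reject_reasons=[reason],
    )


RESIDUE_CHECK_TYPES = {"cutC", "cntA_yeaW", "grdI", "mtmB", "mtbB"}
MTTB_SUPERFAMILY = "mttB_superfamily"  # joint label for the mttB/mtxB branch


def curate_gene(
    candidate: SeqRecord,
    gene_type: str,
    config: CurationConfig,
    nt_context: Optional[tuple[SeqRecord, tuple[int, int], str]] = None,
    clade_context: Optional[set[str]] = None,
) -> GeneAssignment:
    """Run one candidate through one gene type's curation pipeline.

    Steps: >``min_bits`` homolog screen against the type's seeds; clade /
    nearest-reference placement (``clade_context`` may carry a precomputed
    set of candidate ids that passed NJ clade placement for this type);
    then the per-type rule (residue check, or the MTTB superfamily split).
    Evidence is recorded on the returned assignment either way.
    """
    tc = config.for_type(gene_type)
    hits = homology.screen_homologs([candidate], tc.seeds, config.params, config.min_bits)
    if not hits:
        return GeneAssignment(
            candidate_id=candidate.id,
            gene_type=None,
            length_aa=len(candidate),
            reject_reasons=["bitscore_below_threshold"],
        )
    _, _, bits = hits[0]

    clade_pass: Optional[bool] = None
    refs_pos = tc.references_positive or tc.seeds
    if clade_context is not None:
        clade_pass = candidate.id in clade_context
    elif candidate.id in {r.id for r in refs_pos}:
        clade_pass = True  # the candidate is itself a reference
    elif len(refs_pos) + len(tc.references_negative) + 1 >= 4:
        placed = homology.nj_clade_assign(
            [candidate], refs_pos, tc.references_negative, config.params
        )
        clade_pass = candidate.id in placed
    else:
        placed = homology._nearest_positive(
            [candidate], refs_pos, tc.references_negative, config.params
        )
        clade_pass = candidate.id in placed
    if not clade_pass:
        return GeneAssignment(
            candidate_id=candidate.id,
            gene_type=None,
            bitscore=bits,
            clade_pass=False,
            length_aa=len(candidate),
            reject_reasons=["outside_reference_clade"],
        )

    if gene_type in ("mttB", "mtxB", MTTB_SUPERFAMILY):
        if tc.profile is None or tc.profile.pyl_column is None:
            raise ValueError(f"gene type {gene_type!r}: profile with pyl_column required")
        assignment = classify_mttb_superfamily(
            candidate,
            anchor=tc.profile.anchor,
            pyl_column=tc.profile.pyl_column,
            nt_context=nt_context,
            min_len_aa=config.mttb_min_len_aa,
            min_anchor_fraction=config.min_anchor_fraction,
            params=config.params,
            bitscore=bits,
        )
        assignment.clade_pass = True
        return assignment

    if tc.profile is None:
        raise ValueError(f"gene type {gene_type!r}: residue profile required")
    ok, matched, failed = homology.check_residues(candidate, tc.profile, config.params)
    if not ok:
        return GeneAssignment(
            candidate_id=candidate.id,
            gene_type=None,
            bitscore=bits,
            clade_pass=True,
            residues_pass=False,
            length_aa=len(candidate),
            reject_reasons=[f"residue_fail:{','.join(map(str, failed))}"],
        )
    return GeneAssignment(
        candidate_id=candidate.id,
        gene_type=gene_type,
        bitscore=bits,
        clade_pass=True,
        residues_pass=True,
        length_aa=len(candidate),
    )


def curate_all(
    candidates: Sequence[SeqRecord],
    config: CurationConfig,
    nt_contexts: Optional[dict[str, tuple[SeqRecord, tuple[int, int], str]]] = None,
) -> list[GeneAssignment]:
    """Assess every candidate against every configured gene type.

    A candidate accepted by exactly one type keeps that assignment; one
    accepted by several is rejected as ambiguous.  Candidates accepted by
    no type carry the reject evidence of their best-bitscore attempt.
    """
    nt_contexts = nt_contexts or {}
    # phase 1: per-type homolog screen, so each type's clade placement runs
    # once over all of that type's screened candidates
    screened: dict[str, list[SeqRecord]] = {}
    for gtype, tc in config.types.items():
        hits = homology.screen_homologs(candidates, tc.seeds, config.params, config.min_bits)
        screened[gtype] = [cand for cand, _, _ in hits]
    # phase 2: clade placement per type (NJ when enough sequences)
    clade_sets: dict[str, set[str]] = {}
    for gtype, cands in screened.items():
        tc = config.for_type(gtype)
        refs_pos = tc.references_positive or tc.seeds
        if not cands:
            clade_sets[gtype] = set()
        elif len(cands) + len(refs_pos) + len(tc.references_negative) >= 4:
            clade_sets[gtype] = homology.nj_clade_assign(
                cands, refs_pos, tc.references_negative, config.params
            )
        else:
            clade_sets[gtype] = homology._nearest_positive(
                cands, refs_pos, tc.references_negative, config.params
            )
    # phase 3: per-candidate type rules; a candidate accepted under several
    # pipelines with the same final label keeps it, conflicting labels reject
    results: list[GeneAssignment] = []
    for cand in candidates:
        accepted: list[GeneAssignment] = []
        rejected: list[GeneAssignment] = []
        for gtype in config.types:
            a = curate_gene(
                cand,
                gtype,
                config,
                nt_context=nt_contexts.get(cand.id),
                clade_context=clade_sets[gtype],
            )
            (accepted if a.accepted else rejected).append(a)
        labels = {a.gene_type for a in accepted}
        if len(labels) == 1:
            results.append(max(accepted, key=lambda a: a.bitscore))
        elif len(labels) > 1:
            best = max(accepted, key=lambda a: a.bitscore)
            results.append(
                GeneAssignment(
                    candidate_id=cand.id,
                    gene_type=None,
                    bitscore=best.bitscore,
                    length_aa=len(cand),
                    reject_reasons=["ambiguous"],
                )
            )
        else:
            best = max(rejected, key=lambda a: a.bitscore)
            results.append(best)
    return results


def load_curation_config(path) -> CurationConfig:
    """Load a curation config from YAML.

    Layout (paths relative to the config file; positions 0-based)::

        min_bits: 60
        mttb_min_len_aa: 360
        types:
          cutC:
            seeds: cutC_seeds.faa
            anchor: cutC_anchor.faa          # single record
            required: ["120:G", "300:C"]     # position:allowed-residues
            references_positive: cutC_refs.faa
          mttB:
            seeds: mttb_seeds.faa
            anchor: mttb_anchor.faa
            pyl_column: 230
    """
    import yaml

    from .seq_io import read_fasta

    path = __import__("pathlib").Path(path)
    cfg = yaml.safe_load(path.read_text())
    base = path.parent

    def fasta(rel):
        return read_fasta(base / rel, moltype="protein")

    types: dict[str, GeneTypeConfig] = {}
    for gtype, entry in cfg["types"].items():
        seeds = fasta(entry["seeds"])
        profile = None
        if "anchor" in entry:
            (anchor,) = fasta(entry["anchor"])
            required = []
            for spec_str in entry.get("required", []):
                pos, allowed = spec_str.split(":")
                required.append((int(pos), frozenset(allowed)))
            profile = ResidueProfile(
                gene_type=gtype,
                anchor=anchor,
                required=required,
                pyl_column=entry.get("pyl_column"),
            )
        types[gtype] = GeneTypeConfig(
            gene_type=gtype,
            seeds=seeds,
            profile=profile,
            references_positive=(
                fasta(entry["references_positive"])
                if "references_positive" in entry
                else []
            ),
            references_negative=(
                fasta(entry["references_negative"])
                if "references_negative" in entry
                else []
            ),
        )
    return CurationConfig(
        types=types,
        min_bits=float(cfg.get("min_bits", 60.0)),
        mttb_min_len_aa=int(cfg.get("mttb_min_len_aa", MTTB_MIN_LEN_AA)),
        min_anchor_fraction=float(cfg.get("min_anchor_fraction", 0.8)),
    )


@dataclass
class GenomeClassification:
    genome_id: str
    status: Literal["proatherogenic", "non_TMA", "both", "none"]
    inventory: dict[str, int]


def classify_genome(
    genome_id: str, assignments: Sequence[GeneAssignment]
) -> GenomeClassification:
    """Classify one genome's TMA status from its curated gene inventory.

    Presence of any TMA-producing gene type makes the genome
    proatherogenic; any demethylase makes it non-TMA producing; one of
    each makes it both; an empty inventory is none.  Order of assignments
    and gene copy number do not change the status.
    """
    inventory = Counter(a.gene_type for a in assignments if a.accepted)
    roles = {gene_role(g) for g in inventory}
    if roles == {PROATHEROGENIC, NON_TMA}:
        status = "both"
    elif roles == {PROATHEROGENIC}:
        status = "proatherogenic"
    elif roles == {NON_TMA}:
        status = "non_TMA"
    else:
        status = "none"
    return GenomeClassification(genome_id=genome_id, status=status, inventory=dict(inventory))
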