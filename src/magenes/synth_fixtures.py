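"""Synthetic data generators: planted-gene scaffolds, identity-controlled
protein families, case/control cohort simulators, and the reactor dosing
mass-balance helper.

Every generator is deterministic under its seed.  The planted-gene
scaffolds provide ground truth for the curation pipeline: each gene type
gets its own random ancestor protein (mttB carries one pyrrolysine),
candidates are point-mutated family members reverse-translated with random
synonymous codons, and mttB genes are planted with a genuine in-frame TAG
at the Pyl position so that standard ORF calling truncates them and only
amber read-through recovers the full gene.

The cohort simulator draws negative-binomial counts with a planted
case/control fold change per TMA role — proatherogenic genes enriched and
mttB depleted in cases, the effect directions the disease cohort showed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .homology import DEFAULT_PARAMS, ResidueProfile, ScoringParams
from .ma_curation import CurationConfig, GeneTypeConfig
from .seq_io import CODON_TABLE, CountMatrix, GENE_TYPES, SeqRecord, gene_role

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Synonymous codons per amino acid (standard code); 'O' is the amber codon.
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_CODONS_BY_AA["O"] = ["TAG"]


@dataclass
class PlantedGene:
    gene_type: str
    start: int
    end: int  # forward-strand, half-open, stop codon included
    strand: Literal["+", "-"]
    amber_offsets: list[int]  # codon indices read through as Pyl
    protein: str


@dataclass
class PlantedTruth:
    scaffold_id: str
    genes: list[PlantedGene]

    def __post_init__(self) -> None:
        spans = sorted((g.start, g.end) for g in self.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted gene spans overlap")
        for g in self.genes:
            if (g.gene_type == "mttB") != bool(g.amber_offsets):
                raise ValueError("amber offsets must be nonempty iff gene type is mttB")


def random_protein(length: int, rng: np.random.Generator, start_met: bool = True) -> str:
    body = "".join(rng.choice(list(AA20), size=length - 1))
    return ("M" + body) if start_met else "".join(rng.choice(list(AA20), size=length))


def make_family(
    ancestor: str | SeqRecord,
    n: int,
    identity_target: float,
    seed: int,
    protect: Sequence[int] = (),
    id_prefix: str = "fam",
) -> list[SeqRecord]:
    """Point-mutated copies of an ancestor at a controlled identity.

    Exactly ``round((1 - identity_target) * L)`` positions are substituted
    per copy (never the first residue or any ``protect`` position), so the
    measured identity to the ancestor is within rounding of the target.
    """
    if not (0.0 < identity_target <= 1.0):
        raise ValueError("identity_target must be in (0, 1]")
    anc = ancestor.upper if isinstance(ancestor, SeqRecord) else ancestor.upper()
    rng = np.random.default_rng(seed)
    L = len(anc)
    n_mut = int(round((1.0 - identity_target) * L))
    mutable = [i for i in range(1, L) if i not in set(protect) and anc[i] != "O"]
    if n_mut > len(mutable):
        raise ValueError("identity target incompatible with protected positions")
    out = []
    for i in range(n):
        chars = list(anc)
        sites = rng.choice(mutable, size=n_mut, replace=False)
        for s in sites:
            choices = [a for a in AA20 if a != chars[s]]
            chars[s] = choices[rng.integers(len(choices))]
        out.append(
            SeqRecord(
                id=f"{id_prefix}_{i}",
                residues="".join(chars),
                moltype="protein",
            )
        )
    return out


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous coding sequence; 'O' becomes the amber codon TAG."""
    codons = []
    for aa in protein.upper():
        opts = _CODONS_BY_AA[aa]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def _random_intergenic(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


#: Hard-stop guard: TAA in all three frames, and its own reverse complement,
#: so no ORF can run across a planted-gene boundary on either strand and
#: every planted call starts at the planted start codon.
STOP_GUARD = "TTAATTAATTAA"


def _revcomp(nt: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return nt.translate(comp)[::-1]


def plant_genes(
    spec: Sequence[tuple[str, str]],  # (gene_type, protein)
    seed: int,
    spacer_len: int = 150,
    scaffold_id: str = "synthetic_scaffold",
) -> tuple[SeqRecord, PlantedTruth]:
    """Plant proteins as genes on one synthetic scaffold.

    Each protein is reverse-translated with random synonymous codons
    (pyrrolysine -> TAG), given an ATG start and TAA stop, and placed on
    alternating strands separated by random intergenic spacers.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[PlantedGene] = []
    pos = 0

    def emit(fragment: str) -> None:
        nonlocal pos
        parts.append(fragment)
        pos += len(fragment)

    emit(_random_intergenic(spacer_len, rng))
    for k, (gene_type, protein) in enumerate(spec):
        prot = protein.upper()
        if not prot.startswith("M"):
            prot = "M" + prot[1:]
        cds = reverse_translate(prot, rng) + "TAA"
        cds = "ATG" + cds[3:]
        strand = "+" if k % 2 == 0 else "-"
        placed = cds if strand == "+" else _revcomp(cds)
        emit(STOP_GUARD)
        start, end = pos, pos + len(cds)
        amber = [i for i, aa in enumerate(prot) if aa == "O"]
        genes.append(
            PlantedGene(
                gene_type=gene_type,
                start=start,
                end=end,
                strand=strand,
                amber_offsets=amber,
                protein=prot,
            )
        )
        emit(placed)
        emit(STOP_GUARD)
        emit(_random_intergenic(spacer_len, rng))
    scaffold = SeqRecord(id=scaffold_id, residues="".join(parts), moltype="nucleotide")
    return scaffold, PlantedTruth(scaffold_id=scaffold_id, genes=genes)


def shuffle_protein(protein: str, rng: np.random.Generator) -> str:
    """Residue-shuffled decoy: same composition and length, homology destroyed."""
    chars = [c for c in protein.upper() if c != "O"]
    rng.shuffle(chars)
    return "".join(chars)


# ---------------------------------------------------------------------------
# Curation benchmark
# ---------------------------------------------------------------------------

#: Realistic protein lengths (aa) per gene type.
GENE_LENGTHS_AA = {
    "cutC": 440,
    "cntA_yeaW": 400,
    "grdI": 420,
    "mttB": 460,  # pyrrolysine-containing
    "mtxB": 470,  # non-Pyl superfamily member, > 360 aa by definition
    "mtmB": 450,
    "mtbB": 430,
}

PYL_POSITION = 230  # 0-based residue index of 'O' in the synthetic mttB ancestor


@dataclass
class CurationBenchmark:
    scaffolds: list[SeqRecord]
    truth: list[PlantedTruth]
    decoys: list[SeqRecord]
    config: CurationConfig
    ancestors: dict[str, SeqRecord]


def make_ancestors(seed: int = 7) -> dict[str, SeqRecord]:
    """One random ancestor protein per gene type; mttB and mtxB share a
    superfamily backbone (mttB carries 'O' at the Pyl column, mtxB a
    leucine there) so the MTTB split is a genuine decision."""
    rng = np.random.default_rng(seed)
    anc: dict[str, SeqRecord] = {}
    for gtype in GENE_TYPES:
        if gtype == "mtxB":
            continue
        L = GENE_LENGTHS_AA[gtype]
        prot = random_protein(L, rng)
        if gtype == "mttB":
            prot = prot[:PYL_POSITION] + "O" + prot[PYL_POSITION + 1 :]
        anc[gtype] = SeqRecord(id=f"{gtype}_anchor", residues=prot, moltype="protein")
    # mtxB: same backbone as mttB minus Pyl, padded to its own length
    mttb = anc["mttB"].residues
    pad = random_protein(GENE_LENGTHS_AA["mtxB"] - len(mttb) + 1, rng, start_met=False)
    mtxb = mttb[:PYL_POSITION] + "L" + mttb[PYL_POSITION + 1 :] + pad[1:]
    anc["mtxB"] = SeqRecord(id="mtxB_anchor", residues=mtxb, moltype="protein")
    return anc


#: Active-site positions required per residue-checked type (0-based, on the
#: synthetic ancestors). These stand in for the catalytic residues real
#: profiles would pin (e.g. the glycyl radical Gly/Cys of CutC or the
#: Rieske motif of CntA/YeaW) and are protected from mutation in families.
PROFILE_POSITIONS = {
    "cutC": [120, 121, 300],
    "cntA_yeaW": [80, 81, 95],
    "grdI": [150, 151],
    "mtmB": [200, 201],
    "mtbB": [180, 181],
}


def make_benchmark_config(
    ancestors: dict[str, SeqRecord],
    seed: int = 11,
    n_refs: int = 3,
    ref_identity: float = 0.85,
    params: ScoringParams = DEFAULT_PARAMS,
) -> CurationConfig:
    """Curation config over the synthetic ancestors: the ancestor plus a
    small family of mutated references serve as seeds and clade references;
    residue profiles pin the protected positions."""
    types: dict[str, GeneTypeConfig] = {}
    for i, gtype in enumerate(GENE_TYPES):
        anchor = ancestors[gtype]
        protect = list(PROFILE_POSITIONS.get(gtype, []))
        if gtype in ("mttB", "mtxB"):
            protect.append(PYL_POSITION)
        refs = make_family(
            anchor,
            n_refs,
            ref_identity,
            seed=seed + 13 * i,
            protect=protect,
            id_prefix=f"{gtype}_ref",
        )
        if gtype in PROFILE_POSITIONS:
            required = [
                (p, frozenset({anchor.residues[p]})) for p in PROFILE_POSITIONS[gtype]
            ]
            profile = ResidueProfile(gene_type=gtype, anchor=anchor, required=required)
        else:
            profile = ResidueProfile(
                gene_type=gtype, anchor=ancestors["mttB"], required=[], pyl_column=PYL_POSITION
            )
        types[gtype] = GeneTypeConfig(
            gene_type=gtype,
            seeds=[anchor] + refs[:1],
            profile=profile,
            references_positive=[anchor] + refs,
        )
    return CurationConfig(types=types, params=params)


def make_curation_benchmark(
    seed: int = 42,
    n_genes: int = 40,
    n_decoys: int = 40,
    n_mttb: int = 6,
    candidate_identity: float = 0.9,
    genes_per_scaffold: int = 5,
) -> CurationBenchmark:
    """The fixed default benchmark: planted genes across all 7 types
    (including amber-containing mttB) on synthetic scaffolds, plus
    residue-shuffled decoys."""
    rng = np.random.default_rng(seed)
    ancestors = make_ancestors(seed=7)
    config = make_benchmark_config(ancestors, seed=11)
    # allocate gene types: n_mttb mttB, the rest spread over the other six
    others = [t for t in GENE_TYPES if t != "mttB"]
    gene_types = ["mttB"] * n_mttb + [others[i % len(others)] for i in range(n_genes - n_mttb)]
    planted: list[tuple[str, str]] = []
    for i, gtype in enumerate(gene_types):
        protect = list(PROFILE_POSITIONS.get(gtype, []))
        if gtype in ("mttB", "mtxB"):
            protect.append(PYL_POSITION)
        fam = make_family(
            ancestors[gtype],
            1,
            candidate_identity,
            seed=int(rng.integers(2**31)),
            protect=protect,
            id_prefix=f"{gtype}_cand{i}",
        )
        planted.append((gtype, fam[0].residues))
    scaffolds, truths = [], []
    for chunk_start in range(0, len(planted), genes_per_scaffold):
        chunk = planted[chunk_start : chunk_start + genes_per_scaffold]
        sc, tr = plant_genes(
            chunk,
            seed=int(rng.integers(2**31)),
            scaffold_id=f"scaffold_{chunk_start // genes_per_scaffold}",
        )
        scaffolds.append(sc)
        truths.append(tr)
    decoys = []
    for i in range(n_decoys):
        src_type = gene_types[i % len(gene_types)]
        decoys.append(
            SeqRecord(
                id=f"decoy_{i}",
                residues=shuffle_protein(ancestors[src_type].residues, rng),
                moltype="protein",
            )
        )
    return CurationBenchmark(
        scaffolds=scaffolds, truth=truths, decoys=decoys, config=config, ancestors=ancestors
    )


def run_curation_benchmark(
    bench: CurationBenchmark,
    mode: Literal["standard", "readthrough"] = "readthrough",
    min_aa: int = 100,
) -> dict:
    """Drive the benchmark end to end: ORF calling, curation, truth matching.

    ``mode='readthrough'`` calls ORFs with amber read-through variants and
    supplies nucleotide context so truncated hits can be recalled;
    ``mode='standard'`` withholds both, the way a conventional gene caller
    would, which loses every pyrrolysine gene.

    Returns precision/recall over planted genes (an accepted assignment is
    a true positive iff it overlaps a planted gene of the same type on the
    same strand) plus the per-type recovery breakdown.
    """
    from . import ma_curation, orf_amber

    candidates: list[SeqRecord] = []
    contexts: dict[str, tuple[SeqRecord, tuple[int, int], str]] = {}
    call_spans: dict[str, tuple[str, int, int, str]] = {}
    orf_mode = "both" if mode == "readthrough" else "standard"
    for sc in bench.scaffolds:
        for c in orf_amber.call_orfs(sc, min_aa=min_aa, mode=orf_mode, max_readthroughs=1):
            cid = f"{c.scaffold_id}|{c.start}|{c.end}|{c.strand}|rt{c.n_readthrough}"
            candidates.append(SeqRecord(id=cid, residues=c.protein, moltype="protein"))
            call_spans[cid] = (c.scaffold_id, c.start, c.end, c.strand)
            if mode == "readthrough":
                contexts[cid] = (sc, (c.start, c.end), c.strand)
    candidates.extend(bench.decoys)
    assignments = ma_curation.curate_all(
        candidates, bench.config, nt_contexts=contexts or None
    )
    planted = [
        (t.scaffold_id, g) for t in bench.truth for g in t.genes
    ]
    recovered: set[int] = set()
    n_tp = n_fp = 0
    for a in assignments:
        if not a.accepted:
            continue
        span = call_spans.get(a.candidate_id)
        if span is None:
            n_fp += 1  # a decoy was accepted
            continue
        scid, start, end, strand = span
        hit = False
        for gi, (t_scid, g) in enumerate(planted):
            if (
                t_scid == scid
                and strand == g.strand
                and max(start, g.start) < min(end, g.end)
                and a.gene_type == g.gene_type
            ):
                recovered.add(gi)
                hit = True
        if hit:
            n_tp += 1
        else:
            n_fp += 1
    missed = [planted[gi][1].gene_type for gi in range(len(planted)) if gi not in recovered]
    n_accepted = n_tp + n_fp
    return {
        "n_planted": len(planted),
        "n_candidates": len(candidates),
        "n_accepted": n_accepted,
        "precision": n_tp / n_accepted if n_accepted else 0.0,
        "recall": len(recovered) / len(planted),
        "missed_types": sorted(missed),
        "assignments": assignments,
    }


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimCohortSpec:
    """Case/control count simulation parameters.

    Defaults emulate the disease-cohort effect directions: proatherogenic
    genes enriched (log2 FC +1) and mttB depleted (log2 FC -1) in cases.
    """

    n_case: int = 218
    n_control: int = 187
    genes_per_type: int = 5
    role_log2_effects: dict[str, float] = field(
        default_factory=lambda: {"proatherogenic": 1.0, "mttB": -1.0}
    )
    dispersion: float = 0.3  # NB dispersion (var = mu + dispersion * mu^2)
    base_mean: float = 50.0
    depth_range: tuple[float, float] = (0.5, 2.0)
    gene_length_range: tuple[int, int] = (900, 1500)
    marker_label_shift: float = 0.8  # SD shift of blood markers in cases
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 10 or self.n_control < 10:
            raise ValueError("need >= 10 samples per class")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_cohort(spec: SimCohortSpec) -> tuple[CountMatrix, pd.DataFrame, dict[str, str]]:
    """Simulate a case/control gene count matrix plus sample metadata.

    Returns (counts, metadata, typemap).  Counts are negative binomial with
    per-sample library depth factors; case means are scaled by 2**effect
    for genes whose role (or specific type, for 'mttB') has a planted
    effect.  Metadata has label (1 = case), gender (1 = male, 50/50) and
    blood markers whose means shift with the label.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids, types, lengths, effects = [], {}, [], []
    for gtype in GENE_TYPES:
        for i in range(spec.genes_per_type):
            gid = f"{gtype}_g{i}"
            gene_ids.append(gid)
            types[gid] = gtype
            lengths.append(int(rng.integers(*spec.gene_length_range)))
            eff = spec.role_log2_effects.get(gtype, spec.role_log2_effects.get(gene_role(gtype), 0.0))
            effects.append(eff)
    n = spec.n_case + spec.n_control
    labels = np.array([1] * spec.n_case + [0] * spec.n_control)
    depth = rng.uniform(*spec.depth_range, size=n)
    base = rng.lognormal(mean=np.log(spec.base_mean), sigma=0.5, size=len(gene_ids))
    counts = np.zeros((len(gene_ids), n), dtype=int)
    for gi in range(len(gene_ids)):
        mu = base[gi] * depth * (2.0 ** (effects[gi] * labels))
        r = 1.0 / spec.dispersion
        p = r / (r + mu)
        counts[gi] = rng.negative_binomial(r, p)
    sample_ids = [f"case_{i}" if l == 1 else f"ctrl_{i}" for i, l in enumerate(labels)]
    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=gene_ids),
    )
    gender = rng.integers(0, 2, size=n)
    tg = rng.normal(1.5 + spec.marker_label_shift * labels * 0.5, 0.5)
    ldl = rng.normal(3.0 + spec.marker_label_shift * labels * 0.7, 0.8)
    hdl = rng.normal(1.4 - spec.marker_label_shift * labels * 0.3, 0.3)
    meta = pd.DataFrame(
        {
            "label": labels,
            "gender": gender,
            "triglyceride_mmol_l": tg,
            "ldl_mmol_l": ldl,
            "hdl_mmol_l": hdl,
        },
        index=sample_ids,
    )
    return cm, meta, types


# ---------------------------------------------------------------------------
# Reactor dosing mass balance
# ---------------------------------------------------------------------------

@dataclass
class DoseEvent:
    day: float
    kind: Literal["dose", "sample"]
    value: float  # dose: target concentration (mM); sample: volume removed (mL)


@dataclass
class DosingSchedule:
    initial_volume_ml: float
    events: list[DoseEvent]

    def __post_init__(self) -> None:
        days = [e.day for e in self.events]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("events must be in non-decreasing day order")


def reactor_mass_balance(
    schedule: DosingSchedule,
    de_minimis_mM: float = 0.04,
) -> dict[str, float]:
    """Total substrate added (µmol) under dose-to-target-concentration
    semantics: a dose at c mM into the current volume v mL adds c*v µmol.

    Samplings reduce the working volume, so later doses add less substrate.
    Priming doses at or below ``de_minimis_mM`` are tallied separately and
    excluded from the headline total.  Raises if any event empties the
    vessel.
    """
    v = schedule.initial_volume_ml
    if v <= 0:
        raise ValueError("initial volume must be positive")
    total = 0.0
    priming = 0.0
    for e in schedule.events:
        if e.kind == "sample":
            v -= e.value
            if v <= 0:
                raise ValueError(f"sampling at day {e.day} empties the vessel")
        elif e.kind == "dose":
            amount = e.value * v  # mM * mL = µmol
            if e.value <= de_minimis_mM:
                priming += amount
            else:
                total += amount
        else:
            raise ValueError(f"unknown event kind {e.kind!r}")
    return {"total_umol": total, "priming_umol": priming, "final_volume_ml": v}


def standard_reactor_schedule(initial_volume_ml: float = 10.0) -> DosingSchedule:
    """The published microcosm schedule: 40 µM priming at inoculation, 1 mM
    doses at days 3, 10 and 17, each later dose preceded by a 1 mL sampling."""
    return DosingSchedule(
        initial_volume_ml=initial_volume_ml,
        events=[
            DoseEvent(day=0, kind="dose", value=0.04),
            DoseEvent(day=3, kind="dose", value=1.0),
            DoseEvent(day=10, kind="sample", value=1.0),
            DoseEvent(day=10, kind="dose", value=1.0),
            DoseEvent(day=17, kind="sample", value=1.0),
            DoseEvent(day=17, kind="dose", value=1.0),
        ],
    )
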