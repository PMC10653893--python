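"""Sequence and table I/O plus nucleotide translation with pyrrolysine support.

Pyrrolysine ('O', the 22nd amino acid) is encoded by the amber stop codon
TAG in a minority of methyltransferase genes; ``translate`` therefore takes
an ``amber_mode`` switch so callers can either terminate at TAG (``stop``,
the usual reading) or emit 'O' and continue (``pyl``).

Coordinates everywhere in this package are 0-based, half-open, on the
forward strand.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"O", "X", "*"}

#: Standard genetic code (translation table 1/11 codon assignments, no
#: special start handling). TAG is looked up separately by ``translate``.
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

STOP_CODONS = {"TAA", "TAG", "TGA"}
HARD_STOPS = {"TAA", "TGA"}  # never read through
AMBER = "TAG"


class SeqIOError(ValueError):
    """Malformed sequence or table input."""


#: The seven curated methylated-amine gene types and their TMA roles.
#: cutC (choline TMA-lyase), cntA/yeaW (carnitine/butyrobetaine
#: oxygenase, reported as one label because substrate specificity cannot
#: be read off the sequence) and grdI (betaine reductase) release TMA and
#: are proatherogenic; the MTTB-superfamily demethylases (mttB with
#: pyrrolysine, mtxB without) and the methylamine methyltransferases
#: mtmB/mtbB consume methylated amines without releasing TMA.
PROATHEROGENIC = "proatherogenic"
NON_TMA = "non_TMA"

GENE_TYPE_ROLES: dict[str, str] = {
    "cutC": PROATHEROGENIC,
    "cntA_yeaW": PROATHEROGENIC,
    "grdI": PROATHEROGENIC,
    "mttB": NON_TMA,
    "mtxB": NON_TMA,
    "mtmB": NON_TMA,
    "mtbB": NON_TMA,
}

GENE_TYPES: tuple[str, ...] = tuple(GENE_TYPE_ROLES)


def gene_role(gene_type: str) -> str:
    """Map a gene type to its TMA role; unknown labels raise."""
    try:
        return GENE_TYPE_ROLES[gene_type]
    except KeyError:
        raise SeqIOError(f"unknown gene type {gene_type!r}") from None


@dataclass
class SeqRecord:
    """One nucleotide or protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (may be empty).
    """

    id: str
    residues: str
    description: str = ""
    moltype: Literal["nucleotide", "protein"] = "nucleotide"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        up = self.residues.upper()
        alphabet = NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        bad = set(up) - alphabet
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: invalid {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def upper(self) -> str:
        return self.residues.upper()


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with per-gene nucleotide lengths."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: "pd.DataFrame"  # genes x samples, int
    gene_lengths: "pd.Series"  # bp, indexed by gene_id

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SeqIOError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SeqIOError("duplicate sample ids in count matrix")
        if (self.counts.values < 0).any():
            raise SeqIOError("negative counts")
        if (self.gene_lengths <= 0).any():
            raise SeqIOError("non-positive gene lengths")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def guess_moltype(residues: str) -> Literal["nucleotide", "protein"]:
    """Call a sequence nucleotide iff all its characters are ACGTN."""
    return "nucleotide" if set(residues.upper()) <= NUCLEOTIDE_ALPHABET else "protein"


def read_fasta(
    path: str | Path,
    moltype: Literal["nucleotide", "protein", "auto"] = "auto",
) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file.

    Record ids are the first whitespace token of each header and must be
    unique within the file; record order is preserved.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            mt = guess_moltype(str(rec.seq)) if moltype == "auto" else moltype
            records.append(
                SeqRecord(id=rec.id, residues=str(rec.seq), description=desc, moltype=mt)
            )
    return records


def write_fasta(
    records: Iterable[SeqRecord],
    path: str | Path,
    line_width: int = 60,
    append_stop: bool = False,
) -> None:
    """Write records as FASTA; ``append_stop`` adds a terminal '*' to proteins."""
    bio = []
    for r in records:
        res = r.residues
        if append_stop and r.moltype == "protein" and not res.endswith("*"):
            res = res + "*"
        bio.append(_BioSeqRecord(Seq(res), id=r.id, description=r.description))
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(bio)


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def translate(
    nt: str,
    frame: int = 0,
    amber_mode: Literal["stop", "pyl"] = "stop",
) -> str:
    """Translate a forward-strand nucleotide string codon by codon.

    Plain codon translation with the standard code; no start-codon
    remapping.  TAA/TGA always terminate.  TAG terminates in ``stop`` mode
    and emits pyrrolysine 'O' in ``pyl`` mode.  Codons containing N emit
    'X' (draft scaffolds contain Ns).  Translation stops at the first
    terminator or when fewer than 3 nucleotides remain.
    """
    if frame not in (0, 1, 2):
        raise SeqIOError(f"frame must be 0, 1 or 2, got {frame}")
    up = nt.upper()
    bad = set(up) - NUCLEOTIDE_ALPHABET
    if bad:
        raise SeqIOError(f"invalid nucleotide characters {sorted(bad)}")
    out: list[str] = []
    for i in range(frame, len(up) - 2, 3):
        codon = up[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        if codon in HARD_STOPS:
            break
        if codon == AMBER:
            if amber_mode == "stop":
                break
            out.append("O")
            continue
        out.append(CODON_TABLE[codon])
    return "".join(out)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count table: gene_id, length_bp, then one column per sample."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if df.columns[0] != "gene_id" or df.columns[1] != "length_bp":
        raise SeqIOError(
            "count table must start with columns 'gene_id' and 'length_bp', "
            f"got {list(df.columns[:2])}"
        )
    if df.shape[1] < 3:
        raise SeqIOError("count table has no sample columns")
    gene_ids = df["gene_id"].astype(str).tolist()
    lengths = pd.Series(df["length_bp"].values, index=gene_ids, name="length_bp")
    counts = df.drop(columns=["gene_id", "length_bp"])
    counts.index = pd.Index(gene_ids)
    for col in counts.columns:
        vals = counts[col]
        if not pd.api.types.is_integer_dtype(vals):
            # floats representing integers are fine; true fractions are not
            as_int = vals.astype("float64")
            if not (as_int == as_int.round()).all():
                raise SeqIOError(f"non-integer count in sample {col!r}")
            counts[col] = as_int.astype("int64")
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(c) for c in counts.columns],
        counts=counts.astype("int64"),
        gene_lengths=lengths.astype("int64"),
    )


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "length_bp", matrix.gene_lengths.loc[matrix.gene_ids].values)
    df.insert(0, "gene_id", matrix.gene_ids)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)
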