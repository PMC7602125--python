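"""Data model and TSV readers/writers for protein, site and pair tables.

The on-disk contract is three plain TSV files (optionally preceded by
``#`` comment lines documenting the columns):

``proteins.tsv``
    id, group, sequence, abundance_ppm, idr, go_terms (semicolon-joined),
    and ten 0/1 compartment columns in the fixed order
    Mit, Nuc, Lys, ER, Plm, Gol, End, Ske, Per, Cyt.
``sites.tsv``
    protein_id, position (1-based), condition.
``pairs.tsv``
    id_a, id_b (unordered; canonicalized so that id_a < id_b).

Real inputs are exports assembled from MetOSite-style site databases with
PaxDB abundances and DisProt disorder flags; the ``synthetic`` module
writes the same schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol tolerated in sequences for residues of unknown identity.
UNKNOWN_RESIDUE = "X"

#: Fixed compartment column order for the 10-dimensional localization vector.
COMPARTMENTS = ("Mit", "Nuc", "Lys", "ER", "Plm", "Gol", "End", "Ske", "Per", "Cyt")

#: Oxidation group labels.
GROUPS = ("ex_vivo", "in_vitro", "both", "background")

#: Condition labels for individual MetO sites.
CONDITIONS = ("ex_vivo", "in_vitro")

PROTEIN_COLUMNS = (
    "id",
    "group",
    "sequence",
    "abundance_ppm",
    "idr",
    "go_terms",
) + COMPARTMENTS

MISSING = "NA"


class ValidationError(ValueError):
    """Raised when a table fails validation; carries all offending lines."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} validation error(s):\n" + "\n".join(self.errors)
        )


@dataclass
class ProteinRecord:
    """One protein with its annotations.

    ``abundance_ppm`` and ``idr`` may be ``None`` when the corresponding
    external annotation (PaxDB / DisProt) does not cover the protein;
    analyses exclude missing values rather than imputing them.
    """

    id: str
    sequence: str
    group: str
    abundance_ppm: float | None = None
    idr: bool | None = None
    go_terms: frozenset[str] = field(default_factory=frozenset)
    compartments: tuple[int, ...] = (0,) * 10

    def validate(self) -> list[str]:
        errors = []
        if not self.id:
            errors.append("empty protein id")
        if len(self.sequence) < 1:
            errors.append(f"{self.id}: empty sequence")
        else:
            allowed = set(AMINO_ACIDS + UNKNOWN_RESIDUE)
            bad = sorted(set(self.sequence) - allowed)
            if bad:
                errors.append(f"{self.id}: invalid sequence characters {bad}")
        if self.group not in GROUPS:
            errors.append(f"{self.id}: unknown group {self.group!r}")
        if len(self.compartments) != 10 or any(
            c not in (0, 1) for c in self.compartments
        ):
            errors.append(f"{self.id}: malformed compartment vector")
        if self.abundance_ppm is not None and self.abundance_ppm < 0:
            errors.append(f"{self.id}: negative abundance")
        return errors


@dataclass(frozen=True)
class SiteRecord:
    """One methionine sulfoxide site: protein, 1-based position, condition."""

    protein_id: str
    position: int
    condition: str


@dataclass(frozen=True)
class PairRecord:
    """One unordered co-regulated protein pair, stored with id_a < id_b."""

    id_a: str
    id_b: str

    @classmethod
    def canonical(cls, a: str, b: str) -> "PairRecord":
        if a == b:
            raise ValidationError([f"self-pair ({a}, {b})"])
        return cls(min(a, b), max(a, b))


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_proteins(path: str | Path) -> dict[str, ProteinRecord]:
    """Read and validate a protein table; returns records keyed by id.

    All violations are collected and raised together as a single
    :class:`ValidationError` naming the offending lines.
    """
    path = Path(path)
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValidationError([f"{path}: empty file"])
    cols = header.split("\t")
    if tuple(cols) != PROTEIN_COLUMNS:
        raise ValidationError(
            [f"{path}: header mismatch, expected {list(PROTEIN_COLUMNS)}, got {cols}"]
        )

    records: dict[str, ProteinRecord] = {}
    errors: list[str] = []
    for lineno, line in rows:
        fields_ = line.split("\t")
        if len(fields_) != len(PROTEIN_COLUMNS):
            errors.append(f"line {lineno}: expected {len(PROTEIN_COLUMNS)} fields")
            continue
        pid, group, seq, abun, idr, go = fields_[:6]
        comp_raw = fields_[6:]
        try:
            compartments = tuple(int(c) for c in comp_raw)
        except ValueError:
            errors.append(f"line {lineno}: malformed compartment vector")
            continue
        rec = ProteinRecord(
            id=pid,
            sequence=seq,
            group=group,
            abundance_ppm=None if abun == MISSING else float(abun),
            idr=None if idr == MISSING else bool(int(idr)),
            go_terms=frozenset(t for t in go.split(";") if t),
            compartments=compartments,
        )
        rec_errors = rec.validate()
        if rec_errors:
            errors.extend(f"line {lineno}: {e}" for e in rec_errors)
            continue
        if pid in records:
            errors.append(f"line {lineno}: duplicate id {pid}")
            continue
        records[pid] = rec
    if errors:
        raise ValidationError(errors)
    return records


def write_proteins(records: Iterable[ProteinRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "# one row per protein; go_terms semicolon-joined; "
            "compartment columns are 0/1 flags in the order "
            + ", ".join(COMPARTMENTS)
            + "; NA marks missing abundance/idr\n"
        )
        fh.write("\t".join(PROTEIN_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: r.id):
            abun = MISSING if r.abundance_ppm is None else repr(r.abundance_ppm)
            idr = MISSING if r.idr is None else str(int(r.idr))
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.group,
                        r.sequence,
                        abun,
                        idr,
                        ";".join(sorted(r.go_terms)),
                        *[str(c) for c in r.compartments],
                    ]
                )
                + "\n"
            )


def load_sites(
    path: str | Path, proteins: dict[str, ProteinRecord]
) -> list[SiteRecord]:
    """Read a site table and cross-reference it against loaded proteins.

    Sites at position 1 (initiator methionines) are dropped with a logged
    count; sites whose residue is not methionine, or that reference an
    unknown protein, are validation errors.
    """
    path = Path(path)
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValidationError([f"{path}: empty file"])
    if header.split("\t") != ["protein_id", "position", "condition"]:
        raise ValidationError([f"{path}: header mismatch"])

    sites: list[SiteRecord] = []
    errors: list[str] = []
    n_initiator = 0
    for lineno, line in rows:
        try:
            pid, pos_s, condition = line.split("\t")
            position = int(pos_s)
        except ValueError:
            errors.append(f"line {lineno}: malformed row")
            continue
        if pid not in proteins:
            errors.append(f"line {lineno}: unknown protein id {pid}")
            continue
        if condition not in CONDITIONS:
            errors.append(f"line {lineno}: unknown condition {condition!r}")
            continue
        seq = proteins[pid].sequence
        if position == 1:
            n_initiator += 1
            continue
        if not 1 < position <= len(seq):
            errors.append(f"line {lineno}: position {position} outside {pid}")
            continue
        if seq[position - 1] != "M":
            errors.append(
                f"line {lineno}: residue at {pid}:{position} is "
                f"{seq[position - 1]}, not M"
            )
            continue
        sites.append(SiteRecord(pid, position, condition))
    if n_initiator:
        logger.info("dropped %d initiator-Met sites (position 1)", n_initiator)
    if errors:
        raise ValidationError(errors)
    return sites


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# one row per MetO site; position is 1-based\n")
        fh.write("protein_id\tposition\tcondition\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.condition}\n")


def load_pairs(path: str | Path) -> list[PairRecord]:
    """Read an unordered pair table; canonicalizes order, rejects duplicates."""
    path = Path(path)
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValidationError([f"{path}: empty file"])
    if header.split("\t") != ["id_a", "id_b"]:
        raise ValidationError([f"{path}: header mismatch"])
    pairs: list[PairRecord] = []
    seen: set[PairRecord] = set()
    errors: list[str] = []
    for lineno, line in rows:
        parts = line.split("\t")
        if len(parts) != 2:
            errors.append(f"line {lineno}: malformed row")
            continue
        a, b = parts
        if a == b:
            errors.append(f"line {lineno}: self-pair {a}")
            continue
        pair = PairRecord.canonical(a, b)
        if pair in seen:
            errors.append(f"line {lineno}: duplicate pair ({pair.id_a}, {pair.id_b})")
            continue
        seen.add(pair)
        pairs.append(pair)
    if errors:
        raise ValidationError(errors)
    return pairs


def write_pairs(pairs: Iterable[PairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# unordered co-regulated pairs, canonicalized id_a < id_b\n")
        fh.write("id_a\tid_b\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\n")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Export sequences as FASTA (accession as the record id)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.group) for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def sideload_fasta(proteins: dict[str, ProteinRecord], path: str | Path) -> int:
    """Replace sequences from a FASTA file, matching on the accession token.

    Returns the number of sequences replaced.
    """
    from Bio import SeqIO

    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id.split("|")[1] if "|" in rec.id else rec.id
        if accession in proteins:
            proteins[accession].sequence = str(rec.seq)
            n += 1
    return n


def split_groups(
    proteins: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split into (set A = exclusively ex vivo, set B = exclusively in vitro).

    Proteins labeled ``both`` or ``background`` belong to neither set: all
    comparative analyses contrast the two exclusive oxidation groups.
    """
    proteins = list(proteins)
    a = [p for p in proteins if p.group == "ex_vivo"]
    b = [p for p in proteins if p.group == "in_vitro"]
    return a, b
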