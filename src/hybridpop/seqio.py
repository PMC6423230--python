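"""Reading, validation and transformation of per-locus alignments.

The pipeline works on pre-aligned, phased sequence data: each nuclear locus
is a FASTA alignment with two rows per diploid individual (sample keys
``<individual>/1`` and ``<individual>/2``), each chloroplast locus has one
row per individual.  This module provides the in-memory containers
(:class:`Alignment`, :class:`SampleTable`, :class:`MultilocusDataset`,
:class:`HaplotypeTable`) and the standard transformations used downstream:
haplotype collapsing, multilocus concatenation and simple indel coding.

Coordinates are 0-based half-open internally; user-facing reports convert
to 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGT-N")

Marker = Literal["nuclear", "chloroplast"]


class RaggedAlignmentError(ValueError):
    """Raised when records in one locus alignment differ in length."""


@dataclass
class Alignment:
    """A single-locus multiple sequence alignment.

    rows are ``(sample_key, sequence)`` pairs; every sequence uses the
    alphabet ``{A, C, G, T, -, N}`` and all sequences share one length.
    """

    locus_id: str
    rows: list[tuple[str, str]]
    marker: Marker = "nuclear"

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.locus_id!r} has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            offender = max(self.rows, key=lambda r: abs(len(r[1]) - len(self.rows[0][1])))
            raise RaggedAlignmentError(
                f"ragged alignment {self.locus_id!r}: record {offender[0]!r} "
                f"has length {len(offender[1])}, others differ"
            )
        if self.length == 0:
            raise ValueError(f"alignment {self.locus_id!r} has zero length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def sample_keys(self) -> list[str]:
        return [k for k, _ in self.rows]

    def sequence(self, sample_key: str) -> str:
        for k, s in self.rows:
            if k == sample_key:
                return s
        raise KeyError(sample_key)

    def to_array(self) -> np.ndarray:
        """Return the alignment as a (rows, length) array of single chars."""
        return np.array([list(s) for _, s in self.rows], dtype="U1")

    def used_columns(self) -> np.ndarray:
        """Boolean mask of columns free of gaps and Ns in every row
        (complete-deletion policy for polymorphism statistics)."""
        arr = self.to_array()
        return ~((arr == "-") | (arr == "N")).any(axis=0)

    def subset(self, sample_keys: Sequence[str]) -> "Alignment":
        keys = set(sample_keys)
        rows = [(k, s) for k, s in self.rows if k in keys]
        return Alignment(self.locus_id, rows, self.marker)


@dataclass
class SampleTable:
    """Individual-level metadata: taxon, population (locality) and role."""

    table: pd.DataFrame  # columns: individual_id, taxon, population, role

    ROLES = ("candidate_hybrid", "reference_parent", "outgroup")

    def __post_init__(self) -> None:
        required = {"individual_id", "taxon", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if "role" not in self.table.columns:
            self.table = self.table.assign(role="reference_parent")
        dup = self.table["individual_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate individual ids: {sorted(self.table['individual_id'][dup])}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    def taxon_of(self, individual_id: str) -> str:
        sel = self.table.loc[self.table["individual_id"] == individual_id, "taxon"]
        if sel.empty:
            raise KeyError(individual_id)
        return str(sel.iloc[0])

    def individuals_of(self, taxon: str) -> list[str]:
        return list(self.table.loc[self.table["taxon"] == taxon, "individual_id"])

    @classmethod
    def read(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def individual_of_key(sample_key: str) -> str:
    """Map an alignment sample key to its individual id.

    Nuclear haplotype rows are named ``<individual>/1`` and
    ``<individual>/2``; chloroplast rows carry the bare individual id.
    """
    return sample_key.rsplit("/", 1)[0] if "/" in sample_key else sample_key


@dataclass
class MultilocusDataset:
    """All loci of a study plus the sample metadata."""

    alignments: list[Alignment]
    samples: SampleTable

    def __post_init__(self) -> None:
        known = set(self.samples.individual_ids)
        for aln in self.alignments:
            unknown = {individual_of_key(k) for k in aln.sample_keys} - known
            if unknown:
                raise ValueError(
                    f"locus {aln.locus_id!r}: sample keys resolve to unknown "
                    f"individuals {sorted(unknown)}"
                )

    def loci(self, marker: Marker | None = None) -> list[Alignment]:
        if marker is None:
            return list(self.alignments)
        return [a for a in self.alignments if a.marker == marker]

    def locus(self, locus_id: str) -> Alignment:
        for a in self.alignments:
            if a.locus_id == locus_id:
                return a
        raise KeyError(locus_id)

    def missing_loci(self) -> dict[str, list[str]]:
        """Per individual, the loci at which it has no sequence."""
        out: dict[str, list[str]] = {}
        for ind in self.samples.individual_ids:
            absent = [
                a.locus_id
                for a in self.alignments
                if ind not in {individual_of_key(k) for k in a.sample_keys}
            ]
            if absent:
                out[ind] = absent
        return out


def read_alignment(path: str | Path, marker: Marker = "nuclear",
                   locus_id: str | None = None) -> Alignment:
    """Read one FASTA alignment; uppercase; map unknown characters to N."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    if len(records) < 2:
        raise ValueError(f"alignment needs >= 2 records, got {len(records)}: {path}")
    rows = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            logger.warning(
                "record %s in %s: unknown characters %s mapped to N",
                rec.id, path.name, sorted(bad),
            )
            seq = "".join(c if c in VALID_CHARS else "N" for c in seq)
        rows.append((rec.id, seq))
    return Alignment(locus_id or path.stem, rows, marker)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in aln.rows]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class HaplotypeTable:
    """Distinct sequences of one locus with counts and membership.

    Haplotype ids are ``H1, H2, ...`` in order of first occurrence.
    """

    locus_id: str
    haplotypes: list[tuple[str, str, int, list[str]]]  # (id, seq, count, members)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def haplotype_of(self, sample_key: str) -> str:
        for hid, _, _, members in self.haplotypes:
            if sample_key in members:
                return hid
        raise KeyError(sample_key)

    def index_of(self, sample_key: str) -> int:
        for i, (_, _, _, members) in enumerate(self.haplotypes):
            if sample_key in members:
                return i
        raise KeyError(sample_key)


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes, numbered by first
    occurrence."""
    order: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for key, seq in aln.rows:
        if seq not in order:
            order[seq] = len(order)
            members[seq] = []
        members[seq].append(key)
    haps = [
        (f"H{i + 1}", seq, len(members[seq]), members[seq])
        for seq, i in order.items()
    ]
    return HaplotypeTable(aln.locus_id, haps)


def concatenate(dataset: MultilocusDataset, marker: Marker,
                fill_missing: bool = False) -> Alignment:
    """Concatenate all loci of one marker type into a single alignment.

    Row keys are individual ids (for nuclear data, ``<ind>/1`` and
    ``<ind>/2``).  With ``fill_missing`` an individual absent from a locus
    receives Ns across that locus; otherwise its absence is a hard error.
    """
    loci = dataset.loci(marker)
    if not loci:
        raise ValueError(f"no {marker} loci in dataset")
    # canonical row keys: union over loci, ordered by first appearance
    keys: list[str] = []
    seen = set()
    for aln in loci:
        for k in aln.sample_keys:
            if k not in seen:
                seen.add(k)
                keys.append(k)
    parts: dict[str, list[str]] = {k: [] for k in keys}
    for aln in loci:
        present = dict(aln.rows)
        for k in keys:
            if k in present:
                parts[k].append(present[k])
            elif fill_missing:
                parts[k].append("N" * aln.length)
            else:
                raise ValueError(
                    f"individual {individual_of_key(k)!r} missing from locus "
                    f"{aln.locus_id!r} and fill_missing is disabled"
                )
    locus_id = "+".join(a.locus_id for a in loci)
    return Alignment(locus_id, [(k, "".join(parts[k])) for k in keys], marker)


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as 0-based half-open (start, end) intervals."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def code_indels(aln: Alignment) -> pd.DataFrame:
    """Simple indel coding of alignment gaps.

    Each distinct maximal gap (identical start and end across sequences)
    becomes one presence/absence character.  A sequence scores 1 when it
    carries exactly that gap, 0 when it has ordinary bases there, and
    missing ('?') when one of its own gaps strictly contains the
    character's interval (the state is then unobservable).

    Returns a DataFrame indexed by sample key with one column per indel
    character (named by 1-based inclusive coordinates), values in
    {0, 1} or pd.NA for missing.
    """
    per_row = {key: _gap_runs(seq) for key, seq in aln.rows}
    characters: list[tuple[int, int]] = sorted(
        {run for runs in per_row.values() for run in runs}
    )
    data = {}
    for start, end in characters:
        col = []
        for key, _ in aln.rows:
            runs = per_row[key]
            if (start, end) in runs:
                col.append(1)
            elif any(s <= start and end <= e and (s, e) != (start, end)
                     for s, e in runs):
                col.append(pd.NA)
            else:
                col.append(0)
        data[f"indel_{start + 1}_{end}"] = col
    return pd.DataFrame(data, index=[k for k, _ in aln.rows], dtype="object")


def write_indel_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.fillna("?").to_csv(path, sep="\t")
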