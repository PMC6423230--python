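"""Chloroplast genetic typing and cytonuclear-discordance reporting.

Candidate hybrids are assigned a chloroplast type by nearest-reference
matching: each individual's concatenated cpDNA haplotype is compared
(Hamming distance on gap/N-free columns) against labelled reference
haplotype sets, and the label of the closest set wins; exact ties across
sets are flagged ambiguous rather than resolved arbitrarily.  Because
cpDNA is maternally inherited, the winning label identifies the maternal
lineage of a hybrid.

A cross-tabulation of type by locality reproduces specimen-count tables,
and a discordance report compares each individual's biparental nuclear
cluster membership against its maternal chloroplast label — hybrid
individuals show mixed nuclear ancestry, introgressed individuals show
one-sided nuclear ancestry with the other side's chloroplast.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admixture import ClusterPosterior
from .seqio import SampleTable

__all__ = [
    "CpTypeAssignment",
    "assign_cp_type",
    "CountTable",
    "count_table",
    "discordance_report",
]


@dataclass
class CpTypeAssignment:
    """Per-individual chloroplast type calls."""

    table: pd.DataFrame  # index individual; columns type, nearest_taxon,
                         # distance, ambiguous

    def label_of(self, individual: str) -> str | None:
        row = self.table.loc[individual]
        return None if row["ambiguous"] else str(row["type"])


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    ok = ~np.isin(aa, [b"-", b"N"]) & ~np.isin(bb, [b"-", b"N"])
    return int((aa[ok] != bb[ok]).sum())


def assign_cp_type(candidates: Mapping[str, str],
                   reference_sets: Mapping[str, Sequence[str]]) -> CpTypeAssignment:
    """Type candidate cp haplotypes by minimum Hamming distance.

    ``candidates`` maps individual id to its concatenated cp sequence;
    ``reference_sets`` maps a type label to the reference cp sequences of
    that side.  Gap/N columns are excluded pairwise.  An exact distance
    tie across different sets yields an ambiguity flag and no label.
    """
    if len(reference_sets) < 2:
        raise ValueError("need at least 2 reference sets")
    for label, seqs in reference_sets.items():
        if not seqs:
            raise ValueError(f"empty reference set {label!r}")
    rows = []
    for ind, seq in candidates.items():
        best: list[tuple[int, str]] = []
        for label, refs in sorted(reference_sets.items()):
            d = min(_hamming(seq, r) for r in refs)
            best.append((d, label))
        dmin = min(d for d, _ in best)
        winners = sorted({lab for d, lab in best if d == dmin})
        ambiguous = len(winners) > 1
        rows.append({
            "individual_id": ind,
            "type": None if ambiguous else winners[0],
            "nearest_taxon": "|".join(winners),
            "distance": dmin,
            "ambiguous": ambiguous,
        })
    return CpTypeAssignment(
        pd.DataFrame(rows).set_index("individual_id"))


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * digits),
                                           rounding=ROUND_HALF_UP))


@dataclass
class CountTable:
    """Type x locality specimen counts with totals and percentages."""

    counts: pd.DataFrame        # index type, columns locality
    excluded: int               # individuals without an unambiguous type

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def overall_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def percentages(self) -> pd.Series:
        """Share of each type among all typed individuals, percent,
        rounded half-up to one decimal."""
        total = self.overall_total
        if total == 0:
            return pd.Series(dtype=float)
        return self.row_totals.map(
            lambda c: _round_half_up(100.0 * c / total))

    def frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out["Percent"] = self.percentages()
        return out


def count_table(assignment: CpTypeAssignment | pd.DataFrame,
                samples: SampleTable) -> CountTable:
    """Cross-tabulate assigned types by sampling locality.

    Ambiguous/unassigned individuals are excluded from the table and
    reported in ``excluded``.  Totals are always recomputed from the
    table's own cells.
    """
    table = assignment.table if isinstance(assignment, CpTypeAssignment) else assignment
    meta = samples.table.set_index("individual_id")
    typed = table[~table["ambiguous"].astype(bool)]
    excluded = len(table) - len(typed)
    if typed.empty:
        return CountTable(pd.DataFrame(), excluded)
    missing = set(typed.index) - set(meta.index)
    if missing:
        raise ValueError(f"no locality for individuals: {sorted(missing)}")
    localities = meta.loc[typed.index, "population"]
    counts = pd.crosstab(typed["type"], localities)
    counts.index.name = "type"
    counts.columns.name = "locality"
    return CountTable(counts, excluded)


def discordance_report(q: ClusterPosterior, cp: CpTypeAssignment,
                       cluster_sides: Mapping[int, str],
                       threshold: float | None = 0.9,
                       reference_individuals: Sequence[str] = (),
                       ) -> pd.DataFrame:
    """Individuals whose nuclear and chloroplast ancestries disagree.

    ``cluster_sides`` maps nuclear cluster index to the cp type label
    expected for a pure member of that cluster.  An individual is
    reported when (a) its maximum cluster membership falls below the
    purity threshold (admixed nuclear genome — the hybrid pattern), or
    (b) its modal cluster's expected cp side differs from its assigned
    cp label (the introgression pattern).  Ambiguously typed individuals
    are skipped.

    The purity threshold is either a fixed value (default 0.9, the usual
    purebred cutoff in hybrid-zone practice) or, when ``threshold`` is
    None, calibrated on ``reference_individuals`` of known pure origin:
    any individual whose maximum membership falls below the smallest
    reference membership is treated as admixed.  Calibrating on known
    purebreds adapts the cutoff to the marker panel's resolving power.
    """
    if threshold is None:
        if not reference_individuals:
            raise ValueError("threshold=None needs reference_individuals")
        ref_q = [float(q.Q[q.individuals.index(i)].max())
                 for i in reference_individuals]
        threshold = min(ref_q)
    shared = [i for i in q.individuals if i in cp.table.index]
    rows = []
    for ind in shared:
        if bool(cp.table.loc[ind, "ambiguous"]):
            continue
        qi = q.Q[q.individuals.index(ind)]
        modal = int(np.argmax(qi))
        qmax = float(qi[modal])
        cp_label = str(cp.table.loc[ind, "type"])
        expected = cluster_sides.get(modal)
        if qmax < threshold:
            pattern = "hybrid"
        elif expected is not None and expected != cp_label:
            pattern = "introgression"
        else:
            continue
        rows.append({
            "individual_id": ind, "pattern": pattern,
            "modal_cluster": modal, "modal_q": qmax,
            "expected_cp": expected, "observed_cp": cp_label,
        })
    return pd.DataFrame(rows, columns=["individual_id", "pattern",
                                       "modal_cluster", "modal_q",
                                       "expected_cp", "observed_cp"])
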