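"""Lineage-specific protein divergence from a three-taxon alignment.

Two ingroup paralogs/lineages (A, B) are compared against an outgroup (O).
Amino-acid substitutions are placed on the terminal A and B branches by
parsimony: a column where A differs while B = O is a substitution on the A
lineage, and symmetrically for B.  Columns where all three residues differ
have no unique parsimony placement and are reported as ambiguous.  The
one-degree-of-freedom relative-rate test then compares the two lineage counts
m1 and m2 with the statistic chi2 = (m1 - m2)^2 / (m1 + m2).

"Alignable" positions are columns with no gap in any of the three sequences;
in-frame deletions are reported as maximal gap runs private to one ingroup
lineage (or shared by both, i.e. placed on the internal branch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "ThreeTaxonAlignment",
    "DomainMap",
    "RelativeRateResult",
    "RelativeRateModel",
    "RelativeRateResults",
    "Deletion",
    "classify_columns",
    "tajima_1d_test",
    "domain_counts",
    "find_deletions",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
_LEGAL = AMINO_ACIDS | {GAP, "X", "*"}

STATES = ("identical", "subst_A", "subst_B", "subst_O", "ambiguous", "gapped")


@dataclass
class ThreeTaxonAlignment:
    """Aligned amino-acid sequences for ingroups A, B and outgroup O."""

    seq_A: str
    seq_B: str
    seq_O: str
    names: tuple = ("A", "B", "O")
    column_states: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a, b, o = self.seq_A.upper(), self.seq_B.upper(), self.seq_O.upper()
        if not (len(a) == len(b) == len(o)):
            raise ValueError(
                "aligned sequences must have equal length: "
                f"{len(a)}, {len(b)}, {len(o)}"
            )
        for name, seq in zip(self.names, (a, b, o)):
            bad = [i for i, ch in enumerate(seq) if ch not in _LEGAL]
            if bad:
                raise ValueError(
                    f"illegal characters in {name} at positions {bad[:10]}"
                )
        self.seq_A, self.seq_B, self.seq_O = a, b, o

    def __len__(self) -> int:
        return len(self.seq_A)

    @property
    def n_alignable(self) -> int:
        """Columns with no gap in any of the three sequences."""
        return sum(
            GAP not in col
            for col in zip(self.seq_A, self.seq_B, self.seq_O)
        )

    @classmethod
    def from_fasta(cls, path, ingroup_a=None, ingroup_b=None, outgroup=None):
        """Read a 3-record aligned FASTA; roles assigned by id or by order."""
        from Bio import SeqIO

        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if len(records) != 3:
            raise ValueError(f"expected 3 aligned records, got {len(records)}")
        if ingroup_a is None:
            ids = list(records)
            ingroup_a, ingroup_b, outgroup = ids
        for role, rid in (("ingroup_a", ingroup_a), ("ingroup_b", ingroup_b),
                          ("outgroup", outgroup)):
            if rid not in records:
                raise ValueError(f"{role} id {rid!r} not among {list(records)}")
        return cls(records[ingroup_a], records[ingroup_b], records[outgroup],
                   names=(ingroup_a, ingroup_b, outgroup))


def classify_columns(aln: ThreeTaxonAlignment) -> ThreeTaxonAlignment:
    """Fill per-column parsimony states on a three-taxon alignment.

    gap anywhere -> gapped; all equal -> identical; A differs while B = O ->
    subst_A; B differs while A = O -> subst_B; O differs while A = B ->
    subst_O; all three distinct -> ambiguous.
    """
    states = []
    for a, b, o in zip(aln.seq_A, aln.seq_B, aln.seq_O):
        if GAP in (a, b, o):
            states.append("gapped")
        elif a == b == o:
            states.append("identical")
        elif a != b and b == o:
            states.append("subst_A")
        elif b != a and a == o:
            states.append("subst_B")
        elif o != a and a == b:
            states.append("subst_O")
        else:
            states.append("ambiguous")
    aln.column_states = states
    return aln


@dataclass(frozen=True)
class RelativeRateResult:
    """Tajima's 1-df relative-rate test on two lineage substitution counts."""

    m1: int
    m2: int
    chi2: float
    p: float
    n_alignable: int = 0
    df: int = 1

    def summary(self) -> str:
        return (
            f"relative-rate test: m1={self.m1}, m2={self.m2}, "
            f"chi2(1) = {self.chi2:.2f}, P = {self.p:.3g}"
            + (f" ({self.n_alignable} alignable positions)"
               if self.n_alignable else "")
        )


def tajima_1d_test(m1: int, m2: int, n_alignable: int = 0) -> RelativeRateResult:
    """chi2 = (m1 - m2)^2 / (m1 + m2) against chi-square with 1 df.

    Under equal rates on the two lineages, the m1 + m2 lineage-specific
    substitutions fall on either lineage with probability 1/2 each.
    m1 = m2 = 0 returns chi2 = 0, p = 1.
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("substitution counts must be nonnegative")
    if int(m1) != m1 or int(m2) != m2:
        raise ValueError("substitution counts must be integers")
    m1, m2 = int(m1), int(m2)
    total = m1 + m2
    if total == 0:
        stat, p = 0.0, 1.0
    else:
        stat = (m1 - m2) ** 2 / total
        p = float(chi2_dist.sf(stat, df=1))
    return RelativeRateResult(m1=m1, m2=m2, chi2=float(stat), p=p,
                              n_alignable=n_alignable)


@dataclass
class DomainMap:
    """Named protein domains as lists of 0-based half-open column ranges.

    PB1 and PB2 must lie within the PBD when all three are present; kinase,
    linker and PBD must be mutually disjoint.
    """

    domains: dict

    def __post_init__(self) -> None:
        for name, ranges in self.domains.items():
            for start, stop in ranges:
                if start < 0 or stop < start:
                    raise ValueError(f"bad range ({start}, {stop}) in {name}")
        self._check_structure()

    def _columns(self, name: str) -> set:
        return {
            c for start, stop in self.domains[name] for c in range(start, stop)
        }

    def _check_structure(self) -> None:
        d = self.domains
        if "PBD" in d:
            pbd = self._columns("PBD")
            for sub in ("PB1", "PB2"):
                if sub in d and not self._columns(sub) <= pbd:
                    raise ValueError(f"{sub} must lie within PBD")
        core = [n for n in ("kinase", "linker", "PBD") if n in d]
        seen = set()
        for name in core:
            cols = self._columns(name)
            if cols & seen:
                raise ValueError(f"domain {name} overlaps another core domain")
            seen |= cols

    def validate_against(self, aln_length: int) -> None:
        for name, ranges in self.domains.items():
            for start, stop in ranges:
                if stop > aln_length:
                    raise ValueError(
                        f"domain {name} range ({start}, {stop}) exceeds "
                        f"alignment length {aln_length}"
                    )

    @classmethod
    def from_json(cls, path) -> "DomainMap":
        """Load from JSON of name -> [[start, stop], ...], 1-based inclusive
        coordinates in the file, converted to 0-based half-open internally."""
        with open(path) as fh:
            raw = json.load(fh)
        domains = {
            name: [(int(s) - 1, int(e)) for s, e in ranges]
            for name, ranges in raw.items()
            if not name.startswith("_")  # annotation keys like _comment
        }
        return cls(domains)


def domain_counts(aln: ThreeTaxonAlignment, domain_map: DomainMap) -> pd.DataFrame:
    """Per-domain lineage substitution counts and relative-rate tests.

    Returns a DataFrame indexed by domain name (plus a "whole" row) with
    columns m1, m2, n_alignable, chi2, p.
    """
    if aln.column_states is None:
        classify_columns(aln)
    domain_map.validate_against(len(aln))
    states = np.asarray(aln.column_states)

    def count(cols) -> tuple:
        sub = states[cols]
        m1 = int((sub == "subst_A").sum())
        m2 = int((sub == "subst_B").sum())
        n_align = int((sub != "gapped").sum())
        return m1, m2, n_align

    rows = {}
    all_cols = np.arange(len(aln))
    rows["whole"] = count(all_cols)
    for name in domain_map.domains:
        cols = sorted(domain_map._columns(name))
        rows[name] = count(np.asarray(cols, dtype=int))
    out = []
    for name, (m1, m2, n_align) in rows.items():
        res = tajima_1d_test(m1, m2, n_alignable=n_align)
        out.append(
            {"domain": name, "m1": m1, "m2": m2, "n_alignable": n_align,
             "chi2": res.chi2, "p": res.p}
        )
    return pd.DataFrame(out).set_index("domain")


@dataclass(frozen=True)
class Deletion:
    """A maximal gap run attributed to one lineage ('A', 'B' or 'shared')."""

    lineage: str
    start: int
    length: int


def find_deletions(aln: ThreeTaxonAlignment) -> list:
    """Maximal gap runs private to one ingroup (outgroup has residues).

    Runs gapped in exactly one ingroup while the outgroup holds residues are
    deletions on that terminal lineage; runs gapped in both ingroups but not
    the outgroup are 'shared' (parsimony places the loss on the internal
    branch).  Columns gapped in the outgroup are not reported.
    """
    def pattern(i: int) -> str:
        a = aln.seq_A[i] == GAP
        b = aln.seq_B[i] == GAP
        o = aln.seq_O[i] == GAP
        if o:
            return "none"
        if a and b:
            return "shared"
        if a:
            return "A"
        if b:
            return "B"
        return "none"

    out = []
    i, n = 0, len(aln)
    while i < n:
        pat = pattern(i)
        if pat == "none":
            i += 1
            continue
        j = i
        while j < n and pattern(j) == pat:
            j += 1
        out.append(Deletion(lineage=pat, start=i, length=j - i))
        i = j
    return out


class RelativeRateModel:
    """Relative-rate analysis of a classified three-taxon protein alignment.

    Parameters
    ----------
    alignment : ThreeTaxonAlignment
    domain_map : DomainMap, optional
        Named column intervals; per-domain tests are reported when given.
    """

    def __init__(self, alignment: ThreeTaxonAlignment, domain_map=None):
        self.alignment = alignment
        self.domain_map = domain_map

    def fit(self) -> "RelativeRateResults":
        aln = classify_columns(self.alignment)
        states = pd.Series(aln.column_states)
        m1 = int((states == "subst_A").sum())
        m2 = int((states == "subst_B").sum())
        overall = tajima_1d_test(m1, m2, n_alignable=aln.n_alignable)
        per_domain = (
            domain_counts(aln, self.domain_map)
            if self.domain_map is not None
            else None
        )
        return RelativeRateResults(
            model=self,
            overall=overall,
            per_domain=per_domain,
            deletions=find_deletions(aln),
            state_counts=states.value_counts().to_dict(),
        )


@dataclass
class RelativeRateResults:
    model: RelativeRateModel
    overall: RelativeRateResult
    per_domain: pd.DataFrame | None
    deletions: list
    state_counts: dict

    @property
    def divergence_fraction(self) -> float:
        """Fraction of alignable positions divergent on the faster lineage
        (m1, lineage A)."""
        return self.overall.m1 / self.overall.n_alignable

    def deleted_residues(self, lineage: str) -> int:
        return sum(d.length for d in self.deletions if d.lineage == lineage)

    def column_table(self) -> pd.DataFrame:
        aln = self.model.alignment
        return pd.DataFrame(
            {
                "column": np.arange(len(aln)),
                aln.names[0]: list(aln.seq_A),
                aln.names[1]: list(aln.seq_B),
                aln.names[2]: list(aln.seq_O),
                "state": aln.column_states,
            }
        )

    def summary(self) -> str:
        a, b, o = self.model.alignment.names
        lines = [
            f"Three-taxon relative-rate analysis (outgroup: {o})",
            f"  lineage A = {a}, lineage B = {b}",
            f"  alignable positions: {self.overall.n_alignable}",
            "  " + self.overall.summary(),
            f"  divergence on A: {100 * self.divergence_fraction:.0f}% "
            "of alignable positions",
        ]
        if self.per_domain is not None:
            lines.append("")
            lines.append(self.per_domain.to_string(
                float_format=lambda v: f"{v:.4g}"))
        if self.deletions:
            lines.append("")
            for d in self.deletions:
                lines.append(
                    f"  deletion on {d.lineage}: columns "
                    f"{d.start}..{d.start + d.length - 1} ({d.length} aa)"
                )
        return "\n".join(lines)
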