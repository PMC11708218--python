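"""McDonald-Kreitman test from in-frame multi-strain codon alignments.

Two species' alignments (aligned to each other, same coordinates) are scanned
codon by codon.  A nucleotide position segregating within a species yields a
polymorphic record for that species; a position where both species are
monomorphic and share no allele yields a fixed-difference record.  Each
record's effect (synonymous vs nonsynonymous) is scored in codon context;
codons carrying several changes are scored by averaging over all minimal
mutational pathways (Nei-Gojobori style), giving fractional counts.

The 2x2 table contrasts nonsynonymous/synonymous counts of fixed differences
(Dn, Ds) against polymorphism within a focal species (Pn, Ps).  Under
neutrality Dn/Ds = Pn/Ps; an excess of nonsynonymous fixed differences
(neutrality index NI = (Pn/Ps)/(Dn/Ds) < 1, alpha = 1 - NI > 0) indicates
adaptive fixation.  Significance uses the two-sided Fisher exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

__all__ = [
    "CODON_TABLE",
    "SpeciesAlignment",
    "SiteRecord",
    "MKTable",
    "MKModel",
    "MKResults",
    "classify_codon_sites",
    "build_mk_table",
    "mk_exact_test",
    "fisher_exact_2x2",
    "g_test_2x2",
]

# standard genetic code; stops map to '*'
from Bio.Data.CodonTable import unambiguous_dna_by_id

_tab = unambiguous_dna_by_id[1]
CODON_TABLE = dict(_tab.forward_table)
CODON_TABLE.update({c: "*" for c in _tab.stop_codons})

_NUCS = set("ACGT")


@dataclass
class SpeciesAlignment:
    """In-frame aligned coding sequences for the strains of one species."""

    species_name: str
    sequences: list

    def __post_init__(self) -> None:
        seqs = [s.upper() for s in self.sequences]
        if len(seqs) < 1:
            raise ValueError("need at least one sequence")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("all sequences must have equal length")
        if length % 3 != 0:
            raise ValueError(
                f"alignment length {length} is not divisible by 3 "
                "(frame violation)"
            )
        self.sequences = seqs

    def __len__(self) -> int:
        return len(self.sequences[0])

    @property
    def n_strains(self) -> int:
        return len(self.sequences)

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def codon_column(self, k: int) -> list:
        return [s[3 * k: 3 * k + 3] for s in self.sequences]

    @classmethod
    def from_fasta(cls, path, species_name=None) -> "SpeciesAlignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(
            species_name=species_name or str(path),
            sequences=[str(r.seq) for r in records],
        )


@dataclass(frozen=True)
class SiteRecord:
    """One changed nucleotide position: its kind and fractional effect.

    syn + nonsyn = 1 for a single change; fractional splits arise from
    pathway averaging in multi-hit codons.
    """

    codon: int
    position: int  # 0..2 within the codon
    kind: str  # polymorphic_sp1 | polymorphic_sp2 | fixed
    syn: float
    nonsyn: float


def _pathway_effects(c_from: str, c_to: str) -> dict:
    """Average syn/nonsyn effect of each differing position between two
    codons over all minimal mutational pathways, skipping pathways that pass
    through a stop codon (standard pathway-counting convention).  Returns
    {position: (syn_frac, nonsyn_frac)}."""
    diff = [i for i in range(3) if c_from[i] != c_to[i]]
    if not diff:
        return {}
    acc = {i: [0.0, 0.0] for i in diff}
    n_paths = 0
    for order in permutations(diff):
        cur = c_from
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c_to[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" and nxt != c_to:
                blocked = True
                break
            syn = CODON_TABLE[cur] == CODON_TABLE[nxt]
            steps.append((pos, syn))
            cur = nxt
        if blocked:
            continue
        n_paths += 1
        for pos, syn in steps:
            acc[pos][0 if syn else 1] += 1.0
    if n_paths == 0:
        # every route passes a stop; fall back to direct per-position scoring
        for pos in diff:
            nxt = c_from[:pos] + c_to[pos] + c_from[pos + 1:]
            syn = CODON_TABLE[c_from] == CODON_TABLE.get(nxt, None)
            acc[pos] = [1.0 if syn else 0.0, 0.0 if syn else 1.0]
        return {i: tuple(v) for i, v in acc.items()}
    return {i: (v[0] / n_paths, v[1] / n_paths) for i, v in acc.items()}


def _consensus(codons: list) -> str:
    """Per-position majority codon (ties broken alphabetically)."""
    out = []
    for i in range(3):
        counts = {}
        for c in codons:
            counts[c[i]] = counts.get(c[i], 0) + 1
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def _polymorphic_records(codons: list, kind: str, codon_index: int) -> list:
    """Records for segregating positions within one species at one codon."""
    distinct = sorted(set(codons))
    if len(distinct) == 1:
        return []
    records = []
    if len(distinct) == 2:
        effects = _pathway_effects(distinct[0], distinct[1])
        for pos, (syn, nonsyn) in sorted(effects.items()):
            records.append(
                SiteRecord(codon_index, pos, kind, syn, nonsyn)
            )
        return records
    # >2 haplotypes: score each non-consensus allele on the consensus
    # background, averaging per position over the alternate alleles
    cons = _consensus(codons)
    for pos in range(3):
        alleles = sorted({c[pos] for c in codons} - {cons[pos]})
        if not alleles:
            continue
        syn_acc = nonsyn_acc = 0.0
        for alt in alleles:
            mutant = cons[:pos] + alt + cons[pos + 1:]
            if CODON_TABLE[cons] == CODON_TABLE[mutant]:
                syn_acc += 1.0
            else:
                nonsyn_acc += 1.0
        k = len(alleles)
        records.append(
            SiteRecord(codon_index, pos, kind, syn_acc / k, nonsyn_acc / k)
        )
    return records


def classify_codon_sites(sp1: SpeciesAlignment, sp2: SpeciesAlignment) -> list:
    """Per-codon-column change records for two aligned species.

    Codon columns containing a gap or N in any strain are excluded entirely;
    columns where any strain carries a stop codon are excluded with a
    warning.  Fixed differences are positions monomorphic in both species
    with disjoint alleles, scored between the two species consensus codons.
    """
    if len(sp1) != len(sp2):
        raise ValueError(
            f"species alignments differ in length: {len(sp1)} vs {len(sp2)}"
        )
    records = []
    n_stop = 0
    for k in range(sp1.n_codons):
        col1 = sp1.codon_column(k)
        col2 = sp2.codon_column(k)
        both = col1 + col2
        if any(set(c) - _NUCS for c in both):
            continue  # gap or ambiguous base anywhere: column excluded
        if any(CODON_TABLE[c] == "*" for c in both):
            n_stop += 1
            continue
        records.extend(_polymorphic_records(col1, "polymorphic_sp1", k))
        records.extend(_polymorphic_records(col2, "polymorphic_sp2", k))
        # fixed differences: positions monomorphic in both, disjoint alleles
        cons1, cons2 = _consensus(col1), _consensus(col2)
        fixed_pos = []
        for pos in range(3):
            a1 = {c[pos] for c in col1}
            a2 = {c[pos] for c in col2}
            if len(a1) == 1 and len(a2) == 1 and not (a1 & a2):
                fixed_pos.append(pos)
        if fixed_pos:
            # score along the consensus-to-consensus path restricted to the
            # fixed positions (polymorphic positions stay on the sp1 background)
            c_from = cons1
            c_to = "".join(
                cons2[i] if i in fixed_pos else cons1[i] for i in range(3)
            )
            effects = _pathway_effects(c_from, c_to)
            for pos, (syn, nonsyn) in sorted(effects.items()):
                records.append(SiteRecord(k, pos, "fixed", syn, nonsyn))
    if n_stop:
        warnings.warn(
            f"{n_stop} codon column(s) containing stop codons excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    return records


@dataclass
class MKTable:
    """2x2 McDonald-Kreitman counts and derived statistics."""

    Dn: float
    Ds: float
    Pn: float
    Ps: float
    rounding: str = "round"

    @property
    def NI(self) -> float:
        """Neutrality index (Pn/Ps)/(Dn/Ds); NaN when a denominator is 0."""
        if self.Ps == 0 or self.Ds == 0 or self.Dn == 0:
            return float("nan")
        return (self.Pn / self.Ps) / (self.Dn / self.Ds)

    @property
    def alpha(self) -> float:
        """Estimated fraction of adaptive substitutions, 1 - NI."""
        ni = self.NI
        return float("nan") if math.isnan(ni) else 1.0 - ni

    @property
    def p_value(self) -> float:
        if self.rounding == "keep":
            return g_test_2x2(self.Dn, self.Ds, self.Pn, self.Ps)
        return mk_exact_test(self)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Div": [self.Dn, self.Ds], "Poly": [self.Pn, self.Ps]},
            index=["Nonsynon.", "Synon."],
        )


def _apply_rounding(x: float, policy: str) -> float:
    if policy == "round":
        return float(math.floor(x + 0.5))  # round half up, not banker's
    if policy == "floor":
        return float(math.floor(x))
    if policy == "keep":
        return float(x)
    raise ValueError(f"unknown rounding policy {policy!r}")


def build_mk_table(records, focal: str = "sp1", rounding: str = "round") -> MKTable:
    """Assemble the 2x2 table from site records.

    Polymorphism counts are restricted to the focal species ("sp1" or
    "sp2"); fractional pathway counts are resolved by ``rounding``
    ("round" half-up, "floor", or "keep" fractional for a G-test).
    """
    if focal not in ("sp1", "sp2"):
        raise ValueError("focal must be 'sp1' or 'sp2'")
    poly_kind = f"polymorphic_{focal}"
    dn = ds = pn = ps = 0.0
    for r in records:
        if r.kind == "fixed":
            dn += r.nonsyn
            ds += r.syn
        elif r.kind == poly_kind:
            pn += r.nonsyn
            ps += r.syn
    return MKTable(
        Dn=_apply_rounding(dn, rounding),
        Ds=_apply_rounding(ds, rounding),
        Pn=_apply_rounding(pn, rounding),
        Ps=_apply_rounding(ps, rounding),
        rounding=rounding,
    )


def fisher_exact_2x2(a, b, c, d) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability is at most that of the observed table (with a 1e-7
    relative tolerance for ties, as in R's fisher.test).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table cells must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def mk_exact_test(table: MKTable) -> float:
    """Two-sided Fisher exact p-value for an integer MK table."""
    cells = (table.Dn, table.Ds, table.Pn, table.Ps)
    for x in cells:
        if int(x) != x:
            raise ValueError(
                "MK table has fractional counts; apply a rounding policy "
                "('round' or 'floor') before the exact test, or use the "
                "'keep' policy with its G-test"
            )
    return fisher_exact_2x2(*cells)


def g_test_2x2(a, b, c, d) -> float:
    """Likelihood-ratio G-test for a 2x2 table; tolerates fractional counts."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    if n == 0 or obs.sum(0).min() == 0 or obs.sum(1).min() == 0:
        return 1.0
    exp = np.outer(obs.sum(1), obs.sum(0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    return float(chi2_dist.sf(g, df=1))


class MKModel:
    """McDonald-Kreitman analysis of two aligned species alignments.

    Parameters
    ----------
    sp1, sp2 : SpeciesAlignment
        In-frame codon alignments, aligned to each other.
    focal : {"sp1", "sp2"}
        Species whose polymorphism enters the 2x2 table (default "sp1").
    """

    def __init__(self, sp1: SpeciesAlignment, sp2: SpeciesAlignment,
                 focal: str = "sp1"):
        self.sp1 = sp1
        self.sp2 = sp2
        self.focal = focal

    def fit(self, rounding: str = "round") -> "MKResults":
        records = classify_codon_sites(self.sp1, self.sp2)
        table = build_mk_table(records, focal=self.focal, rounding=rounding)
        other = "sp2" if self.focal == "sp1" else "sp1"
        table_other = build_mk_table(records, focal=other, rounding=rounding)
        return MKResults(model=self, records=records, table=table,
                         table_other_focal=table_other)


@dataclass
class MKResults:
    model: MKModel
    records: list = field(repr=False, default=None)
    table: MKTable = None
    table_other_focal: MKTable = None

    def record_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"codon": r.codon, "position": r.position, "kind": r.kind,
                 "syn": r.syn, "nonsyn": r.nonsyn}
                for r in self.records
            ]
        )

    def summary(self) -> str:
        t = self.table
        focal_name = (
            self.model.sp1.species_name
            if self.model.focal == "sp1"
            else self.model.sp2.species_name
        )
        ni = t.NI
        lines = [
            "McDonald-Kreitman test "
            f"({self.model.sp1.species_name} vs {self.model.sp2.species_name}; "
            f"polymorphism within {focal_name})",
            t.as_frame().to_string(),
            f"NI = {ni:.4g}" if not math.isnan(ni) else "NI undefined",
            (f"alpha = {t.alpha:.4g}" if not math.isnan(ni)
             else "alpha undefined"),
            f"Fisher exact P = {t.p_value:.3g}"
            if t.rounding != "keep"
            else f"G-test P = {t.p_value:.3g}",
        ]
        return "\n".join(lines)
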