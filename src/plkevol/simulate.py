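"""Synthetic inputs with the statistical structure each analysis assumes.

Two kinds of generators:

* count-planting generators (proteins, codon alignments) place an exact,
  known number of substitutions/polymorphisms at disjoint sites with no
  homoplasy, so the corresponding analysis stage must recover the planted
  quantities exactly;
* distribution generators (expression tables, brood tables) draw from the
  stated stochastic model (lognormal replicate noise, negative-binomial
  broods with lognormal batch/strain intercepts, binomial sex allocation,
  zero-inflated siring) and are recovered within stochastic tolerance.

Every generator is deterministic given (config, seed): identical inputs
give identical outputs.  Fixtures plant counts; they do not model
evolution (no codon substitution models, no coalescent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import ThreeTaxonAlignment
from .expression import ExpressionTable
from .mk import CODON_TABLE, SpeciesAlignment
from .transmission import MeiosisParams, TransmissionModel

__all__ = [
    "ThreeTaxonConfig",
    "MKConfig",
    "ExpressionConfig",
    "ProgenyConfig",
    "simulate_three_taxon_proteins",
    "simulate_mk_alignments",
    "simulate_expression_table",
    "simulate_progeny",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NON_STOP_CODONS = np.array(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)

# planting templates: (ancestral codon, derived codon) pairs realising one
# synonymous or one nonsynonymous single-nucleotide change, no stops involved
_SYN_PAIR = ("GGT", "GGC")      # Gly -> Gly
_NONSYN_PAIR = ("AAA", "AGA")   # Lys -> Arg
_MULTIHIT_PAIR = ("TTT", "GGG")  # Phe -> Gly, three changes, no stop paths

# the six nonoverlapping tissue samples of the source experimental design
DEFAULT_TISSUES = ("digestive", "gonad", "reproductive", "thorax",
                   "abdomen", "head")


@dataclass
class ThreeTaxonConfig:
    """Planted three-taxon protein alignment: exact per-lineage counts."""

    length: int = 567
    m1: int = 80      # substitutions private to ingroup lineage A
    m2: int = 3       # substitutions private to ingroup lineage B
    m_out: int = 0    # substitutions private to the outgroup lineage
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.m1, self.m2, self.m_out) < 0:
            raise ValueError("all counts must be nonnegative")
        if self.m1 + self.m2 + self.m_out > self.length:
            raise ValueError(
                f"m1 + m2 + m_out = {self.m1 + self.m2 + self.m_out} exceeds "
                f"alignment length {self.length}"
            )


def simulate_three_taxon_proteins(config: ThreeTaxonConfig,
                                  seed=None) -> ThreeTaxonAlignment:
    """Random ancestral protein with exactly m1/m2/m_out private changes.

    Changes are planted at disjoint positions (no homoplasy), so column
    classification recovers (m1, m2) exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    anc = rng.choice(_AA, size=config.length)
    positions = rng.choice(
        config.length, size=config.m1 + config.m2 + config.m_out,
        replace=False,
    )
    seqs = {name: anc.copy() for name in "ABO"}
    bounds = np.cumsum([config.m1, config.m2, config.m_out])
    for name, pos in zip(
        "ABO", np.split(positions, bounds[:-1])
    ):
        for p in pos:
            choices = _AA[_AA != anc[p]]
            seqs[name][p] = rng.choice(choices)
    return ThreeTaxonAlignment(
        "".join(seqs["A"]), "".join(seqs["B"]), "".join(seqs["O"]),
        names=("lineage_A", "lineage_B", "outgroup"),
    )


@dataclass
class MKConfig:
    """Planted codon alignments with exact (Pn, Ps, Dn, Ds) counts."""

    n_codons: int = 200
    Pn: int = 10
    Ps: int = 20
    Dn: int = 40
    Ds: int = 20
    n_strains_sp1: int = 30   # focal species strain count
    n_strains_sp2: int = 11
    multi_hit: int = 0        # number of extra triple-difference fixed codons
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.Pn, self.Ps, self.Dn, self.Ds, self.multi_hit)
        if min(counts) < 0:
            raise ValueError("all planted counts must be nonnegative")
        if sum(counts) > self.n_codons:
            raise ValueError(
                f"planted codons ({sum(counts)}) exceed n_codons "
                f"({self.n_codons})"
            )
        if self.n_strains_sp1 < 2:
            raise ValueError("focal species needs >= 2 strains")
        if self.n_strains_sp2 < 1:
            raise ValueError("second species needs >= 1 strain")


def simulate_mk_alignments(config: MKConfig, seed=None):
    """Two species alignments with planted polymorphism and divergence.

    Exactly Pn (Ps) nonsynonymous (synonymous) polymorphic codons within
    species 1 — the derived allele carried by a random nonempty proper
    subset of strains — and Dn (Ds) fixed differences, at disjoint codons,
    one nucleotide change per codon.  With ``multi_hit`` > 0, extra fixed
    codons carry three differences, producing fractional pathway counts.
    Returns (sp1, sp2) as SpeciesAlignment objects.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_codons
    background = rng.choice(_NON_STOP_CODONS, size=n)
    total_planted = (config.Pn + config.Ps + config.Dn + config.Ds
                     + config.multi_hit)
    planted = rng.choice(n, size=total_planted, replace=False)
    splits = np.split(
        planted,
        np.cumsum([config.Pn, config.Ps, config.Dn, config.Ds])[:4],
    )
    pn_pos, ps_pos, dn_pos, ds_pos, mh_pos = splits

    codons1 = [np.array([background[k]] * config.n_strains_sp1)
               for k in range(n)]
    codons2 = [np.array([background[k]] * config.n_strains_sp2)
               for k in range(n)]

    def subset(n_strains: int) -> np.ndarray:
        k = int(rng.integers(1, n_strains))  # nonempty proper subset
        return rng.choice(n_strains, size=k, replace=False)

    for pos, (anc, der) in (
        (pn_pos, _NONSYN_PAIR), (ps_pos, _SYN_PAIR),
    ):
        for k in pos:
            codons1[k] = np.array([anc] * config.n_strains_sp1)
            codons2[k] = np.array([anc] * config.n_strains_sp2)
            codons1[k][subset(config.n_strains_sp1)] = der
    for pos, (anc, der) in (
        (dn_pos, _NONSYN_PAIR), (ds_pos, _SYN_PAIR),
        (mh_pos, _MULTIHIT_PAIR),
    ):
        for k in pos:
            codons1[k] = np.array([anc] * config.n_strains_sp1)
            codons2[k] = np.array([der] * config.n_strains_sp2)

    seq1 = ["".join(codons1[k][i] for k in range(n))
            for i in range(config.n_strains_sp1)]
    seq2 = ["".join(codons2[k][i] for k in range(n))
            for i in range(config.n_strains_sp2)]
    return (
        SpeciesAlignment("species1", seq1),
        SpeciesAlignment("species2", seq2),
    )


@dataclass
class ExpressionConfig:
    """Planted expression profiles with exact noiseless tau targets.

    tau_targets maps gene_id -> target tau in [0, 1]; each such gene gets a
    profile with one peak tissue at log-level ``peak_log`` and the others at
    peak_log * (1 - tau), whose analytic tau equals the target exactly
    before replicate noise.  Background genes get uniform-random taus.
    """

    tau_targets: dict = field(default_factory=dict)
    n_background: int = 50
    tissues: tuple = DEFAULT_TISSUES
    n_replicates: int = 4
    noise_sd: float = 0.1   # lognormal sd on the NRC scale
    peak_log: float = 2.0   # log10(NRC_TS + 1) in the peak tissue
    seed: int = 0

    def __post_init__(self) -> None:
        for g, t in self.tau_targets.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"tau target for {g} outside [0, 1]: {t}")
        if len(self.tissues) < 2:
            raise ValueError("need at least two tissues")


def planted_profile(tau: float, n_tissues: int, peak_log: float) -> np.ndarray:
    """Log-scale profile whose tau is exactly the target (peak first)."""
    S = np.full(n_tissues, peak_log * (1.0 - tau))
    S[0] = peak_log
    return S


def simulate_expression_table(config: ExpressionConfig,
                              seed=None) -> ExpressionTable:
    """Expression table with planted tau genes plus random background genes.

    Replicates multiply the planted NRC by lognormal noise with sd
    ``noise_sd``; both sexes share each gene's tissue profile.  Peak tissues
    rotate across genes so no tissue is systematically the peak.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tissues = list(config.tissues)
    n_t = len(tissues)
    genes, profiles = [], []
    for gene, tau in config.tau_targets.items():
        genes.append(gene)
        profiles.append(planted_profile(tau, n_t, config.peak_log))
    for i in range(config.n_background):
        genes.append(f"bg{i:04d}")
        tau = rng.uniform(0.0, 1.0)
        peak = rng.uniform(0.5, 3.0)
        prof = planted_profile(tau, n_t, peak)
        profiles.append(np.roll(prof, int(rng.integers(n_t))))
    columns = pd.MultiIndex.from_tuples(
        [
            (sex, t, r)
            for sex in ("female", "male")
            for t in tissues
            for r in range(1, config.n_replicates + 1)
        ],
        names=["sex", "tissue", "replicate"],
    )
    data = np.empty((len(genes), len(columns)))
    for gi, prof in enumerate(profiles):
        nrc = 10.0 ** prof - 1.0
        for ci, (sex, tissue, rep) in enumerate(columns):
            base = nrc[tissues.index(tissue)]
            noise = np.exp(rng.normal(0.0, config.noise_sd)) if base > 0 else 1.0
            data[gi, ci] = base * noise
    return ExpressionTable(pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                                        columns=columns))


@dataclass
class ProgenyConfig:
    """Brood-table generator: negative-binomial broods, binomial sexes.

    Per transgene: n_males, mean brood size, NB dispersion (shape k; larger
    is less overdispersed), zero-inflation (probability a male sires
    nothing), and p_female — either a fixed probability or derived from a
    MeiosisParams forward computation.  Batch and strain act as lognormal
    random intercepts on brood size with sds sd_batch and sd_strain.
    """

    transgenes: tuple = ("transgeneA", "transgeneB")
    n_males: int = 24
    mean_brood: float = 60.0
    dispersion: float = 5.0
    zero_inflation: float = 0.2
    p_female: float | dict = 0.5
    meiosis_params: MeiosisParams | None = None
    brood_effects: dict = field(default_factory=dict)  # transgene -> + mean shift
    n_batches: int = 3
    n_strains: int = 2
    sd_batch: float = 0.3
    sd_strain: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        if self.dispersion <= 0 or self.mean_brood <= 0:
            raise ValueError("mean_brood and dispersion must be positive")


def simulate_progeny(config: ProgenyConfig, seed=None) -> pd.DataFrame:
    """One ProgenyRecord row per male: transgene, strain, batch, counts."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.meiosis_params is not None:
        p_female_default = TransmissionModel(
            config.meiosis_params).expectation().female_fraction
    else:
        p_female_default = None
    batch_eff = rng.normal(0.0, config.sd_batch, size=config.n_batches)
    rows = []
    for tg in config.transgenes:
        if isinstance(config.p_female, dict):
            p_f = config.p_female[tg]
        elif p_female_default is not None:
            p_f = p_female_default
        else:
            p_f = config.p_female
        strain_eff = rng.normal(0.0, config.sd_strain, size=config.n_strains)
        shift = config.brood_effects.get(tg, 0.0)
        for i in range(config.n_males):
            batch = int(rng.integers(config.n_batches))
            strain = int(rng.integers(config.n_strains))
            if rng.uniform() < config.zero_inflation:
                brood = 0
            else:
                mu = max(
                    (config.mean_brood + shift)
                    * np.exp(batch_eff[batch] + strain_eff[strain]),
                    1e-9,
                )
                k = config.dispersion
                brood = int(rng.negative_binomial(k, k / (k + mu)))
            n_female = int(rng.binomial(brood, p_f)) if brood else 0
            rows.append(
                {
                    "male_id": f"{tg}_m{i:03d}",
                    "transgene": tg,
                    "strain": f"{tg}_s{strain}",
                    "batch": f"b{batch}",
                    "n_female": n_female,
                    "n_male": brood - n_female,
                }
            )
    return pd.DataFrame(rows)
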