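"""Expression breadth across tissues: the tau tissue-specificity index.

Expression input is a table of normalized read counts (NRC), genes x samples,
where each sample is a (sex, tissue, replicate) combination.  Per gene and
sex-by-tissue group the replicate median is taken (NRC_TS), log-transformed as
log10(NRC_TS + 1), and summarised over the N tissues of one sex as

    tau = sum_i (1 - S_i / S_max) / (N - 1),

with S_i the log-scale expression in tissue i and S_max = max_i S_i.
tau = 0 means equal expression in every tissue (broad); tau = 1 means
expression confined to a single tissue (narrow).  A gene with S_max = 0 has
no defined tau and is flagged rather than forced to 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

__all__ = [
    "ExpressionTable",
    "TauProfile",
    "ExpressionBreadthModel",
    "ExpressionBreadthResults",
    "median_by_group",
    "log_expression",
    "compute_tau",
    "expression_percentile",
]

SEXES = ("female", "male")


@dataclass
class ExpressionTable:
    """Nonnegative NRC values per gene x (sex, tissue, replicate) sample.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene_id), samples in columns.  Columns must be
        a MultiIndex (sex, tissue, replicate) or strings ``sex.tissue.rep``
        with sex in {f, m, female, male} and rep a positive integer.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df.columns, pd.MultiIndex):
            df = df.copy()
            df.columns = pd.MultiIndex.from_tuples(
                [_parse_sample_name(c) for c in df.columns],
                names=["sex", "tissue", "replicate"],
            )
        else:
            df = df.copy()
            df.columns = pd.MultiIndex.from_tuples(
                [(_canon_sex(s), t, int(r)) for s, t, r in df.columns],
                names=["sex", "tissue", "replicate"],
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dups}")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.values = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.values.columns.get_level_values("tissue")))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{s}.{t}.{r}" for s, t, r in out.columns]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _canon_sex(sex: str) -> str:
    s = str(sex).lower()
    if s in ("f", "female"):
        return "female"
    if s in ("m", "male"):
        return "male"
    raise ValueError(f"unrecognised sex label: {sex!r}")


def _parse_sample_name(name: str) -> tuple[str, str, int]:
    parts = str(name).split(".")
    if len(parts) < 3:
        raise ValueError(
            f"sample column {name!r} is not of the form sex.tissue.replicate"
        )
    sex, tissue, rep = parts[0], ".".join(parts[1:-1]), parts[-1]
    rep_i = int(rep)
    if rep_i < 1:
        raise ValueError(f"replicate must be a positive integer in {name!r}")
    return _canon_sex(sex), tissue, rep_i


def median_by_group(table: ExpressionTable) -> pd.DataFrame:
    """Median NRC per gene across replicates of each sex-by-tissue group.

    Returns a DataFrame with genes in rows and a (sex, tissue) MultiIndex in
    columns (NRC_TS).  Even-sized groups use the midpoint of the two central
    order statistics (the ordinary sample median).
    """
    df = table.values
    grouped = df.T.groupby(level=["sex", "tissue"])
    for key, sub in grouped:
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            raise ValueError(f"empty replicate group for (sex, tissue) = {key}")
    med = grouped.median().T
    med.columns.names = ["sex", "tissue"]
    return med


def log_expression(nrc_ts):
    """log10(NRC_TS + 1); 0 maps to 0 and the map is strictly increasing."""
    x = np.asarray(nrc_ts, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("NRC_TS must be finite")
    if (x < 0).any():
        raise ValueError("NRC_TS must be nonnegative")
    out = np.log10(x + 1.0)
    return out if out.ndim else float(out)


@dataclass
class TauProfile:
    """Per-gene, per-sex tau with its underlying log-scale tissue profile."""

    gene_id: str
    sex: str
    S: np.ndarray
    S_max: float
    tau: float  # NaN when undefined (all-zero profile)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.tau)


def compute_tau(profile, gene_id: str = "", sex: str = "") -> TauProfile:
    """tau index of a log-scale expression profile across N >= 2 tissues.

    ``profile`` holds the already log-transformed values S_i = log10(NRC_TS+1).
    tau = sum(1 - S_i/S_max) / (N - 1).  An all-zero profile (S_max = 0) has
    undefined tau, returned as NaN with a warning.
    """
    S = np.asarray(profile, dtype=float)
    if S.ndim != 1 or S.size < 2:
        raise ValueError("profile must be a vector over N >= 2 tissues")
    if not np.all(np.isfinite(S)):
        raise ValueError("profile values must be finite")
    if (S < 0).any():
        raise ValueError("log-scale profile values must be nonnegative")
    s_max = float(S.max())
    if s_max == 0.0:
        warnings.warn(
            f"tau undefined for all-zero profile (gene {gene_id or '?'})",
            RuntimeWarning,
            stacklevel=2,
        )
        tau = float("nan")
    else:
        tau = float(np.sum(1.0 - S / s_max) / (S.size - 1))
    return TauProfile(gene_id=gene_id, sex=sex, S=S, S_max=s_max, tau=tau)


def expression_percentile(gene_value: float, genome_values) -> float:
    """Mid-rank percentile of a value within a genome-wide distribution.

    Returns 100 * (#strictly below + 0.5 * #equal) / total, deterministic
    under ties.
    """
    genome = np.asarray(genome_values, dtype=float)
    if genome.size == 0:
        raise ValueError("genome-wide distribution is empty")
    return float(percentileofscore(genome, gene_value, kind="mean"))


class ExpressionBreadthModel:
    """Tissue-specificity (tau) analysis of an expression table.

    Parameters
    ----------
    table : ExpressionTable
    tissues : sequence of str, optional
        Tissues entering tau (default: every tissue in the table except any
        named in ``exclude``).  Whole-body samples are excluded from tau by
        default because they overlap every other sample.
    exclude : sequence of str
        Tissue names dropped from the tau computation (default ("wholebody",)).
    focal_genes : sequence of str, optional
        Genes for which percentile placement is reported.
    """

    def __init__(self, table, tissues=None, exclude=("wholebody",),
                 focal_genes=None):
        if not isinstance(table, ExpressionTable):
            table = ExpressionTable(table)
        self.table = table
        avail = table.tissues
        if tissues is None:
            tissues = [t for t in avail if t not in set(exclude)]
        else:
            missing = set(tissues) - set(avail)
            if missing:
                raise ValueError(f"tissues not in table: {sorted(missing)}")
        if len(tissues) < 2:
            raise ValueError("tau needs at least two tissues")
        self.tissues = list(tissues)
        self.focal_genes = list(focal_genes or [])

    def fit(self) -> "ExpressionBreadthResults":
        med = median_by_group(self.table)
        log_med = pd.DataFrame(
            log_expression(med.to_numpy()), index=med.index, columns=med.columns
        )
        rows = []
        profiles = {}
        for sex in SEXES:
            if sex not in log_med.columns.get_level_values("sex"):
                continue
            cols = [(sex, t) for t in self.tissues]
            missing = [c for c in cols if c not in log_med.columns]
            if missing:
                raise ValueError(
                    f"missing (sex, tissue) groups: {missing}"
                )
            sub = log_med.loc[:, cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for gene in sub.index:
                    prof = compute_tau(
                        sub.loc[gene].to_numpy(), gene_id=gene, sex=sex
                    )
                    profiles[(gene, sex)] = prof
                    rows.append(
                        {"gene_id": gene, "sex": sex, "tau": prof.tau,
                         "S_max": prof.S_max}
                    )
        tau_df = pd.DataFrame(rows)
        n_undef = int(tau_df["tau"].isna().sum())
        if n_undef:
            warnings.warn(
                f"tau undefined for {n_undef} all-zero gene profiles",
                RuntimeWarning,
                stacklevel=2,
            )
        return ExpressionBreadthResults(
            model=self, median_nrc=med, log_median=log_med, tau=tau_df,
            profiles=profiles,
        )


@dataclass
class ExpressionBreadthResults:
    """Fitted tau table plus the intermediate median/log matrices."""

    model: ExpressionBreadthModel
    median_nrc: pd.DataFrame
    log_median: pd.DataFrame
    tau: pd.DataFrame
    profiles: dict = field(repr=False, default_factory=dict)

    def tau_of(self, gene_id: str, sex: str) -> float:
        hit = self.tau[(self.tau.gene_id == gene_id) & (self.tau.sex == sex)]
        if hit.empty:
            raise KeyError((gene_id, sex))
        return float(hit.tau.iloc[0])

    def percentiles(self, focal_genes=None) -> pd.DataFrame:
        """Genome-wide percentile of each focal gene's log expression,
        per sex-by-tissue sample."""
        genes = focal_genes if focal_genes is not None else self.model.focal_genes
        rows = []
        for col in self.log_median.columns:
            genome = self.log_median[col].to_numpy()
            for g in genes:
                rows.append(
                    {
                        "gene_id": g,
                        "sex": col[0],
                        "tissue": col[1],
                        "log_expression": float(self.log_median.loc[g, col]),
                        "percentile": expression_percentile(
                            self.log_median.loc[g, col], genome
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Expression breadth (tau) over "
            f"{len(self.model.tissues)} tissues: {', '.join(self.model.tissues)}",
            f"genes: {self.median_nrc.shape[0]}",
            "",
            self.tau.to_string(index=False,
                               float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.tau.copy()
        # per-tissue log expression alongside tau for audit
        for t in self.model.tissues:
            out[f"log_{t}"] = [
                float(self.log_median.loc[g, (s, t)])
                for g, s in zip(out.gene_id, out.sex)
            ]
        out.to_csv(path, sep="\t", index=False)
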