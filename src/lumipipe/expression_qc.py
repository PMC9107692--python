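"""Count-matrix ingest, sample-level QC and normalization.

The pipeline starts from gene-level read counts of a 72-gene targeted panel
(50 subtype genes, 17 immune genes, 5 housekeeping genes). Samples are kept when
fewer than 30% of panel genes have zero counts and the total read count exceeds
10,000; retained counts are converted to counts per million (CPM) within the
panel, log2(x+1)-transformed, then gene-median centered and optionally per-gene
standardized. Both thresholds and the optional transcript-length correction are
explicit parameters so the defaults can be relaxed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config


@dataclass
class ExpressionPanel:
    """Sample x gene count matrix with per-gene role annotation.

    ``counts`` rows are samples, columns are genes. ``gene_roles`` maps every
    gene to one of ``subtype`` / ``immune`` / ``housekeeping``.
    """

    counts: pd.DataFrame
    gene_roles: dict[str, str]
    transcript_lengths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        unknown = [g for g in self.counts.columns if g not in self.gene_roles]
        if unknown:
            raise ValueError(f"genes without a role annotation: {unknown}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.transcript_lengths is not None:
            bad = [g for g, L in self.transcript_lengths.items() if L <= 0]
            if bad:
                raise ValueError(f"non-positive transcript lengths for {bad}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.counts.columns if self.gene_roles[g] == role]

    def write_tsv(self, path) -> None:
        """Write as gene x sample TSV (first column gene symbol, header sample IDs)."""
        self.counts.T.to_csv(path, sep="\t", index_label="gene")


@dataclass
class NormalizedMatrix:
    """Log2-scale expression with an explicit record of the transforms applied."""

    values: pd.DataFrame  # samples x genes, after centering/standardization
    log2: pd.DataFrame  # samples x genes, log2(CPM+1) before centering
    centering: str = "gene-median"  # or "none"
    standardized: bool = False
    zero_variance_genes: list[str] = field(default_factory=list)


def read_counts(
    path,
    gene_roles: dict[str, str] | None = None,
    transcript_lengths: dict[str, float] | None = None,
) -> ExpressionPanel:
    """Read a gene x sample TSV/CSV count matrix into an :class:`ExpressionPanel`.

    The first column holds gene symbols; the header holds sample IDs. Genes
    absent from the role panel are dropped with a warning (never silently);
    a missing housekeeping gene is a hard error because every downstream score
    is referenced against the housekeeping mean.
    """
    gene_roles = dict(gene_roles) if gene_roles is not None else config.default_gene_roles()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)

    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna()]
        if len(bad):
            raise ValueError(f"non-numeric count at gene {bad[0]!r}, sample {col!r}")
        if (coerced < 0).any():
            g = raw.index[(coerced < 0).to_numpy()][0]
            raise ValueError(f"negative count at gene {g!r}, sample {col!r}")
        raw[col] = coerced

    hk = [g for g, r in gene_roles.items() if r == config.ROLE_HOUSEKEEPING]
    missing_hk = sorted(set(hk) - set(raw.index))
    if missing_hk:
        raise ValueError(f"missing housekeeping gene(s): {missing_hk}")

    unknown = [g for g in raw.index if g not in gene_roles]
    if unknown:
        warnings.warn(
            f"{len(unknown)} gene(s) not in the role panel were dropped: {unknown}",
            stacklevel=2,
        )
        raw = raw.drop(index=unknown)

    counts = raw.T  # samples x genes
    counts.index.name = None
    counts.columns.name = None
    roles = {g: gene_roles[g] for g in counts.columns}
    return ExpressionPanel(counts=counts, gene_roles=roles, transcript_lengths=transcript_lengths)


def qc_filter_samples(
    panel: ExpressionPanel,
    max_missing_fraction: float = 0.30,
    min_total_reads: float = 10_000,
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Drop samples failing the missingness or library-size rule.

    A gene is "missing" in a sample when its count is zero. A sample is kept iff
    (zero-count fraction) < ``max_missing_fraction`` AND total reads are strictly
    greater than ``min_total_reads``. Returns the filtered panel and a QC report
    with one row per sample and the reason(s) for any exclusion.
    """
    counts = panel.counts
    missing_frac = (counts == 0).mean(axis=1)
    total = counts.sum(axis=1)
    pass_missing = missing_frac < max_missing_fraction
    pass_reads = total > min_total_reads
    kept = pass_missing & pass_reads

    reasons = []
    for s in counts.index:
        r = []
        if not pass_missing[s]:
            r.append(f"missing_fraction {missing_frac[s]:.3f} >= {max_missing_fraction}")
        if not pass_reads[s]:
            r.append(f"total_reads {total[s]:.0f} <= {min_total_reads:.0f}")
        reasons.append("; ".join(r))
    report = pd.DataFrame(
        {
            "missing_fraction": missing_frac,
            "total_reads": total,
            "retained": kept,
            "exclusion_reason": reasons,
        },
        index=counts.index,
    )
    if not kept.any():
        raise ValueError(f"all samples excluded by QC:\n{report}")
    filtered = ExpressionPanel(
        counts=counts.loc[kept],
        gene_roles=dict(panel.gene_roles),
        transcript_lengths=panel.transcript_lengths,
    )
    return filtered, report


def normalize(
    panel: ExpressionPanel,
    center: bool = True,
    standardize: bool = True,
    use_transcript_lengths: bool = False,
) -> NormalizedMatrix:
    """CPM -> log2(x+1) -> gene-median centering -> optional standardization.

    CPM uses each sample's panel-wide library size. With
    ``use_transcript_lengths`` the counts are first divided by transcript length
    in kb (requires ``panel.transcript_lengths``). Genes with zero variance
    across samples are flagged and left unstandardized rather than divided by
    zero.
    """
    counts = panel.counts.astype(float)
    if use_transcript_lengths:
        if panel.transcript_lengths is None:
            raise ValueError("transcript lengths requested but none attached to the panel")
        missing = [g for g in counts.columns if g not in panel.transcript_lengths]
        if missing:
            raise ValueError(f"no transcript length for gene(s): {missing}")
        kb = pd.Series({g: panel.transcript_lengths[g] / 1e3 for g in counts.columns})
        counts = counts / kb

    libsize = panel.counts.sum(axis=1).astype(float)
    if (libsize == 0).any():
        zeros = libsize.index[libsize == 0].tolist()
        raise ValueError(f"zero library size for sample(s): {zeros}")
    # CPM is taken on the (possibly length-corrected) abundances renormalized to
    # the sample total, so per-sample CPM always sums to 1e6.
    cpm = counts.div(counts.sum(axis=1), axis=0) * 1e6
    log2 = np.log2(cpm + 1.0)

    values = log2
    centering = "none"
    zero_var: list[str] = []
    if center:
        values = log2 - log2.median(axis=0)
        centering = "gene-median"
    did_standardize = False
    if standardize:
        if not center:
            raise ValueError("standardization requires gene-median centering")
        sd = values.std(axis=0, ddof=1)
        zero_var = sd.index[(sd == 0) | sd.isna()].tolist()
        safe = sd.copy()
        safe[(safe == 0) | safe.isna()] = 1.0
        values = values / safe
        did_standardize = True
    return NormalizedMatrix(
        values=values,
        log2=log2,
        centering=centering,
        standardized=did_standardize,
        zero_variance_genes=zero_var,
    )
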