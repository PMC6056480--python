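"""Expression normalization, 2-means binarization, bimodality scoring and
the state-versus-category independence test.

Boolean modelling assumes each gene's expression is bimodal: a low basal
mode and a high active mode separated by a threshold.  Time-course genes
whose distribution shows two modes are split by 1-D k-means (k=2) and each
sample is assigned 1 above the inter-cluster threshold rho.  Unimodal genes
carry no per-sample signal, so they are pooled and 2-means on their
per-gene mean expression assigns a single gene-level state.  A Pearson
chi-square test on the 2x2 table of gene-level state versus gene category
checks that pluripotency factors concentrate in the high state and
differentiation genes in the low state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

TIMECOURSE_KMEANS = "timecourse_kmeans"
UNIMODAL_FALLBACK = "unimodal_fallback"


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV (first column gene symbols).

    Missing values are an error: the binarization has no imputation step.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.isna().any().any():
        bad = matrix.index[matrix.isna().any(axis=1)].tolist()
        raise ValueError(f"missing expression values for genes: {bad}")
    return matrix.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def logcpm_normalize(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count.

    value[g, s] = log2((count[g, s] + prior) / (libsize_s + 2 * prior) * 1e6)

    The pseudo-count keeps all-zero genes finite; doubling every count and
    library size changes values only through the prior term.
    """
    counts = pd.DataFrame(counts).astype(float)
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    libsize = counts.sum(axis=0)
    zero = libsize.index[libsize <= 0].tolist()
    if zero:
        raise ValueError(f"zero library size for samples: {zero}")
    values = np.log2((counts + prior) / (libsize + 2.0 * prior) * 1e6)
    return values


# ---------------------------------------------------------------------------
# Bimodality amplitude
# ---------------------------------------------------------------------------

def bimodality_amplitude(values: Sequence[float], bins: int | None = None,
                         prominence: float = 0.1) -> float:
    """Proportion-of-bimodality statistic in [0, 1].

    A histogram density with ceil(sqrt(n)) bins is lightly smoothed with a
    3-bin binomial kernel (when there are at least 5 bins) and zero-padded
    so boundary point masses register as peaks; peaks must have prominence
    of at least ``prominence`` times the maximum height, which suppresses
    sampling jitter on unimodal data.  With fewer than two peaks the data
    are unimodal and the amplitude is 0.  Otherwise, for the two highest
    peaks with smaller height A_lo and the minimum density A_anti between
    them,

        amplitude = (A_lo - A_anti) / A_lo

    clipped to [0, 1]: 0 for a unimodal sample, 1 for two point masses.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if np.unique(values).size < 2:
        return 0.0
    n_bins = bins if bins is not None else ceil(sqrt(values.size))
    density, _ = np.histogram(values, bins=n_bins, density=True)
    if density.size >= 5:
        density = np.convolve(density, [0.25, 0.5, 0.25], mode="same")
    padded = np.concatenate([[0.0], density, [0.0]])
    peaks, props = find_peaks(padded, prominence=prominence * padded.max())
    if len(peaks) < 2:
        return 0.0
    heights = padded[peaks]
    top = peaks[np.argsort(heights, kind="stable")[::-1][:2]]
    left, right = sorted(top)
    a_lo = min(padded[left], padded[right])
    a_anti = padded[left + 1:right].min()
    return float(np.clip((a_lo - a_anti) / a_lo, 0.0, 1.0))


@dataclass
class BimodalityReport:
    """Per-gene amplitude and the derived unimodal/bimodal flag."""

    amplitude: pd.Series  # gene -> [0, 1]

    @property
    def modality(self) -> pd.Series:
        return self.amplitude.map(
            lambda a: "unimodal" if a == 0.0 else "bimodal")

    def bimodal_genes(self) -> list[str]:
        return self.amplitude.index[self.amplitude > 0].tolist()


def bimodality_report(matrix: pd.DataFrame, **kwargs) -> BimodalityReport:
    amp = pd.Series(
        {g: bimodality_amplitude(matrix.loc[g].values, **kwargs)
         for g in matrix.index},
        name="amplitude",
    )
    return BimodalityReport(amp.loc[matrix.index])


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@dataclass
class BinarizedMatrix:
    """0/1 state assignments with per-gene thresholds rho.

    For ``timecourse_kmeans`` genes, states[g, s] == 1 exactly where the
    expression exceeds rho[g].  ``unimodal_fallback`` genes carry one
    gene-level state replicated across samples; their rho is the pooled
    boundary applied to the gene's mean expression.
    """

    states: pd.DataFrame          # genes x samples, 0/1
    threshold: pd.Series          # gene -> rho
    method: pd.Series             # gene -> method tag

    def gene_states(self) -> pd.Series:
        """One state per gene: majority over samples for time-course genes
        (ties resolve to 0), the assigned state for fallback genes."""
        frac = self.states.mean(axis=1)
        return (frac > 0.5).astype(int)

    def series(self) -> pd.DataFrame:
        """The state matrix, ordered as loaded (columns = time/samples)."""
        return self.states

    def write(self, states_path: str | Path,
              threshold_path: str | Path) -> None:
        self.states.to_csv(states_path, sep="\t", index_label="gene")
        frame = pd.DataFrame({"rho": self.threshold, "method": self.method})
        frame.to_csv(threshold_path, sep="\t", index_label="gene")


def _two_means_split(values: np.ndarray, seed: int) -> tuple[np.ndarray, float]:
    """1-D k-means with k=2 (10 restarts): returns high-cluster membership
    and the inter-cluster threshold (midpoint of max(low), min(high))."""
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    high = int(np.argmax(centers))
    is_high = labels == high
    rho = 0.5 * (values[~is_high].max() + values[is_high].min())
    return is_high, float(rho)


def binarize(matrix: pd.DataFrame, seed: int = 0,
             amplitude_kwargs: Mapping | None = None) -> BinarizedMatrix:
    """Binarize a genes-by-samples expression matrix.

    Bimodal genes (positive bimodality amplitude) are split per sample by
    2-means with the high-mean cluster mapped to 1 and rho the midpoint
    between the clusters.  Unimodal genes are pooled: 2-means over their
    per-gene mean expression assigns one gene-level state (higher group 1).
    Deterministic for a fixed seed and invariant to sample order.
    """
    if matrix.shape[1] < 1 or np.unique(matrix.values).size < 2:
        raise ValueError("need at least 2 distinct expression values")
    report = bimodality_report(matrix, **(amplitude_kwargs or {}))

    states = pd.DataFrame(0, index=matrix.index, columns=matrix.columns,
                          dtype=int)
    threshold = pd.Series(np.nan, index=matrix.index, name="rho")
    method = pd.Series("", index=matrix.index, name="method")

    fallback_genes: list[str] = []
    for gene in matrix.index:
        values = matrix.loc[gene].values.astype(float)
        if report.amplitude[gene] > 0 and np.unique(values).size >= 2:
            is_high, rho = _two_means_split(values, seed)
            # threshold consistency: assign by the threshold itself
            states.loc[gene] = (values > rho).astype(int)
            threshold[gene] = rho
            method[gene] = TIMECOURSE_KMEANS
        else:
            fallback_genes.append(gene)

    if fallback_genes:
        summaries = matrix.loc[fallback_genes].mean(axis=1).values
        if np.unique(summaries).size < 2:
            warnings.warn(
                "unimodal fallback pool has fewer than 2 distinct per-gene "
                "summaries; assigning state 0 to all"
            )
            gene_state = np.zeros(len(fallback_genes), dtype=int)
            rho_pool = float(summaries.max())
        else:
            is_high, rho_pool = _two_means_split(summaries, seed)
            gene_state = is_high.astype(int)
        for g, s in zip(fallback_genes, gene_state):
            states.loc[g] = int(s)
            threshold[g] = rho_pool
            method[g] = UNIMODAL_FALLBACK

    return BinarizedMatrix(states, threshold, method)


# ---------------------------------------------------------------------------
# Chi-square independence test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndependenceTestResult:
    """Pearson chi-square of binary state against gene category."""

    contingency: pd.DataFrame  # 2 x K (state x category)
    statistic: float
    df: int
    p_value: float

    @property
    def n_genes(self) -> int:
        return int(self.contingency.values.sum())


def category_independence_test(states: Mapping[str, int],
                               annotations: Mapping[str, str],
                               categories: Sequence[str] = (
                                   "pluripotency_tf", "differentiation"),
                               correction: bool = False,
                               ) -> IndependenceTestResult:
    """Test whether gene-level binary state depends on gene category.

    Builds the 2xK contingency table over genes annotated with one of
    ``categories`` (default: pluripotency TFs versus differentiation genes)
    and applies Pearson's chi-square; Yates continuity correction is off by
    default and available as a flag.
    """
    states = pd.Series(dict(states))
    table = pd.DataFrame(0, index=[0, 1], columns=list(categories), dtype=int)
    for gene, state in states.items():
        cat = annotations.get(gene)
        if cat in table.columns:
            table.loc[int(state), cat] += 1
    empty = [c for c in table.columns if table[c].sum() == 0]
    if empty:
        raise ValueError(f"no genes in categories: {empty}")
    observed = table.values
    if (observed.sum(axis=1) == 0).any():
        # a degenerate all-0 or all-1 state row: independence holds trivially
        return IndependenceTestResult(table, 0.0, len(categories) - 1, 1.0)
    res = chi2_contingency(observed, correction=correction)
    return IndependenceTestResult(table, float(res.statistic),
                                  int(res.dof), float(res.pvalue))
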