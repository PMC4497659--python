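"""The IUGR/AGA placental growth-factor study: published tables and a
moment-matched synthetic surrogate of its raw data.

The study measured, in 46 newborns (26 appropriate-for-gestational-age, AGA;
20 intra-uterine growth restricted, IUGR), gestational age, total placental
protein content, relative placental gene expression of IGF-I, IGF-2,
IGFBP-1, IGFBP-2 and IL-6, and placental lysate content of IGF-2, IGFBP-2,
TNF-α and IL-6, plus sex and diagnostic class.  The raw per-subject table is
not redistributable; what is public are its per-class means and standard
deviations (:func:`study_group_stats`, with sex counts 11M/9F IUGR and
12M/14F AGA) and the full 15×15 linear correlation matrix over the expanded
variable set (:func:`study_correlation_matrix`).

:func:`surrogate_study_dataset` rebuilds a synthetic stand-in for the raw
table from those published summaries: within each class the sample mean
vector and covariance matrix are matched exactly (per-class SDs as printed,
a shared within-class correlation solved so that the pooled 46-record
correlations reproduce the published matrix).  It reproduces the published
group statistics by construction and the published correlations to ≈0.02,
but being multivariate normal within class it cannot carry skewness or any
nonlinear structure of the real measurements.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .dataset import Dataset

__all__ = [
    "STUDY_VARIABLES",
    "EXPANDED_VARIABLES",
    "CLASS_COLUMNS",
    "study_group_stats",
    "study_sex_counts",
    "study_correlation_matrix",
    "correlation_transcription_discrepancies",
    "surrogate_study_dataset",
    "expand_sex_indicator",
]

#: Column order of the study table: sex once (Male=1), eleven quantitative
#: variables, then the complementary diagnostic indicators.
STUDY_VARIABLES = [
    "Male", "GestAge", "PRO",
    "mRNA_BP1", "mRNA_BP2", "mRNA_IL6", "mRNA_IGF1", "mRNA_IGF2",
    "PLA_IGF2", "PLATNF", "PLAIL6", "PLA_BP2",
    "AGA", "IUGR",
]

#: Variable order of the published correlation matrix, with sex expanded
#: into the complementary Male/Female pair.
EXPANDED_VARIABLES = [
    "Male", "Female", "GestAge", "PRO",
    "mRNA_BP1", "mRNA_BP2", "mRNA_IL6", "mRNA_IGF1", "mRNA_IGF2",
    "PLA_IGF2", "PLATNF", "PLAIL6", "PLA_BP2",
    "AGA", "IUGR",
]

CLASS_COLUMNS = ["AGA", "IUGR"]

_N_AGA, _N_IUGR = 26, 20
_SEX_COUNTS = {"IUGR": (11, 9), "AGA": (12, 14)}  # (male, female)

# IL-6 and IGF-I relative expression are printed with identical group
# statistics and a mutual correlation of 1.00; the surrogate reproduces the
# duplication as printed by copying one column into the other.
_DUPLICATE_OF = {"mRNA_IL6": "mRNA_IGF1"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("autocmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col=0)


def study_group_stats() -> pd.DataFrame:
    """Published per-class mean and SD of each quantitative variable.

    Columns: ``mean_IUGR``, ``mean_AGA``, ``sd_IUGR``, ``sd_AGA``; one row
    per quantitative variable (sex and class indicators excluded).
    """
    return _read("study_group_stats.csv")


def study_sex_counts() -> dict[str, tuple[int, int]]:
    """Published (male, female) counts per diagnostic class."""
    return dict(_SEX_COUNTS)


def study_correlation_matrix(symmetrize: bool = True) -> pd.DataFrame:
    """Published 15×15 linear correlation matrix over the expanded variables.

    The printed table contains exactly one asymmetric pair (see
    :func:`correlation_transcription_discrepancies`); with
    ``symmetrize=True`` (default) the two printed values are averaged.
    """
    r = _read("study_correlations.csv")
    if symmetrize:
        r = (r + r.T) / 2
    return r


def correlation_transcription_discrepancies() -> list[tuple[str, str, float, float]]:
    """Pairs printed asymmetrically in the published correlation matrix.

    Returns ``(row, column, printed_value, printed_transpose)`` for every
    off-diagonal pair whose two printed entries disagree.
    """
    r = _read("study_correlations.csv")
    out = []
    for i, a in enumerate(r.index):
        for j in range(i + 1, len(r.index)):
            b = r.index[j]
            if abs(r.iloc[i, j] - r.iloc[j, i]) > 1e-12:
                out.append((a, b, float(r.iloc[i, j]), float(r.iloc[j, i])))
    return out


def _exact_moment_sample(
    rng: np.random.Generator, n: int, mean: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Gaussian sample whose *sample* mean and covariance (ddof=1) equal the
    targets exactly.  Requires n > dim; works for singular covariances."""
    k = len(mean)
    z = rng.standard_normal((n, k))
    z -= z.mean(axis=0)
    cz = (z.T @ z) / (n - 1)
    z = z @ np.linalg.inv(np.linalg.cholesky(cz)).T
    w, u = np.linalg.eigh((cov + cov.T) / 2)
    root = u @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return mean + z @ root.T


def surrogate_study_dataset(seed: int = 20150709) -> Dataset:
    """Synthetic surrogate of the study's raw 46×14 table.

    Construction: let the published per-class means/SDs define the class
    moments and the published pooled correlations define the total
    covariance; the between-class covariance implied by the class means is
    subtracted and the remaining within-class covariance is solved
    elementwise against the mixture of per-class SD products, assuming the
    two classes share one within-class correlation matrix (projected to the
    nearest positive semi-definite matrix).  Each class is then drawn with
    *exactly* matching sample moments, sex indicators are assigned at the
    published counts, and duplicated expression columns are copied verbatim.

    Returns a :class:`Dataset` with class labels; record ids ``AGA01`` …
    ``IUGR20``; raw (unscaled) values.
    """
    rng = np.random.default_rng(seed)
    stats = study_group_stats()
    rfull = study_correlation_matrix()
    gen_vars = [v for v in stats.index if v not in _DUPLICATE_OF]

    mu_i = stats.loc[gen_vars, "mean_IUGR"].to_numpy()
    mu_a = stats.loc[gen_vars, "mean_AGA"].to_numpy()
    sd_i = stats.loc[gen_vars, "sd_IUGR"].to_numpy()
    sd_a = stats.loc[gen_vars, "sd_AGA"].to_numpy()
    p_i, p_a = _N_IUGR / 46, _N_AGA / 46

    mu = p_i * mu_i + p_a * mu_a
    var_tot = p_i * (sd_i**2 + mu_i**2) + p_a * (sd_a**2 + mu_a**2) - mu**2
    sd_tot = np.sqrt(var_tot)
    r_t = rfull.loc[gen_vars, gen_vars].to_numpy().copy()
    np.fill_diagonal(r_t, 1.0)
    cov_tot = r_t * np.outer(sd_tot, sd_tot)
    cov_between = p_i * np.outer(mu_i - mu, mu_i - mu) + p_a * np.outer(mu_a - mu, mu_a - mu)
    cov_within = cov_tot - cov_between
    # shared within-class correlation, solved against the SD-product mixture
    mix = p_i * np.outer(sd_i, sd_i) + p_a * np.outer(sd_a, sd_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_w = np.where(mix > 1e-12, cov_within / np.where(mix > 1e-12, mix, 1.0), 0.0)
    np.fill_diagonal(r_w, 1.0)
    r_w = np.clip(r_w, -0.99, 0.99)
    np.fill_diagonal(r_w, 1.0)
    w, u = np.linalg.eigh((r_w + r_w.T) / 2)
    r_w = u @ np.diag(np.clip(w, 1e-6, None)) @ u.T
    d = np.sqrt(np.diag(r_w))
    r_w /= np.outer(d, d)

    x_a = _exact_moment_sample(rng, _N_AGA, mu_a, r_w * np.outer(sd_a, sd_a))
    x_i = _exact_moment_sample(rng, _N_IUGR, mu_i, r_w * np.outer(sd_i, sd_i))
    x = np.vstack([x_a, x_i])

    cols = {v: x[:, j] for j, v in enumerate(gen_vars)}
    for dup, src in _DUPLICATE_OF.items():
        cols[dup] = cols[src].copy()

    male = np.zeros(46)
    m_a, _ = _SEX_COUNTS["AGA"]
    m_i, _ = _SEX_COUNTS["IUGR"]
    male[rng.permutation(_N_AGA)[:m_a]] = 1.0
    male[_N_AGA + rng.permutation(_N_IUGR)[:m_i]] = 1.0
    aga = np.concatenate([np.ones(_N_AGA), np.zeros(_N_IUGR)])
    cols.update({"Male": male, "AGA": aga, "IUGR": 1.0 - aga})

    ids = [f"AGA{i+1:02d}" for i in range(_N_AGA)] + [f"IUGR{i+1:02d}" for i in range(_N_IUGR)]
    frame = pd.DataFrame({v: cols[v] for v in STUDY_VARIABLES}, index=ids)
    labels = pd.Series(["AGA"] * _N_AGA + ["IUGR"] * _N_IUGR, index=ids, name="class")
    return Dataset(values=frame, class_labels=labels)


def expand_sex_indicator(ds: Dataset) -> Dataset:
    """Add the complementary ``Female = 1 − Male`` indicator and order the
    columns as in the published correlation matrix."""
    frame = ds.values.copy()
    frame["Female"] = 1.0 - frame["Male"]
    order = [v for v in EXPANDED_VARIABLES if v in frame.columns]
    extras = [c for c in frame.columns if c not in order]
    return Dataset(values=frame[order + extras], class_labels=ds.class_labels,
                   scaled=ds.scaled)
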