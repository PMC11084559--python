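"""Mutational-spectrum tabulation and regression tests.

Substitutions are collapsed to the six strand-symmetric SNV classes
(transitions AT>GC and GC>AT; transversions AT>CG, AT>TA, GC>CG, GC>TA);
in-frame insertions and deletions form two further categories, giving 8
categories in total.  Differences in the spectrum across glucose level
and strain are tested with a baseline-category multinomial logit model
(all categories jointly; likelihood-ratio chi-square with 7 df per
binary predictor) and with per-category binomial logistic models (1 df
per term).  Terms are tested Type-II style: main effects are dropped
from the additive model, the interaction from the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .rate_comparison import chisq_sf

__all__ = [
    "CATEGORIES",
    "SNV_CLASSES",
    "SpectrumTable",
    "ModelTestResult",
    "MultinomialFit",
    "classify_substitution",
    "tabulate_spectrum",
    "relative_frequencies",
    "fit_multinomial",
    "type2_tests_multinomial",
    "fit_binomial_class",
]

SNV_CLASSES = ("AT>GC", "GC>AT", "AT>CG", "AT>TA", "GC>CG", "GC>TA")
CATEGORIES = SNV_CLASSES + ("insertion", "deletion")

_CLASS_OF = {
    ("A", "G"): "AT>GC", ("T", "C"): "AT>GC",
    ("G", "A"): "GC>AT", ("C", "T"): "GC>AT",
    ("A", "C"): "AT>CG", ("T", "G"): "AT>CG",
    ("A", "T"): "AT>TA", ("T", "A"): "AT>TA",
    ("G", "C"): "GC>CG", ("C", "G"): "GC>CG",
    ("G", "T"): "GC>TA", ("C", "A"): "GC>TA",
}


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Strand-collapsed SNV class of a single-base substitution."""
    key = (ref_base.upper(), alt_base.upper())
    if key not in _CLASS_OF:
        raise ValueError(f"not a valid substitution: {ref_base}>{alt_base}")
    return _CLASS_OF[key]


@dataclass(frozen=True)
class SpectrumTable:
    """Counts of the 8 mutation categories per strain x glucose condition.

    ``counts``: DataFrame indexed by (strain, glucose) with the 8 canonical
    categories as columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if list(df.columns) != list(CATEGORIES):
            raise ValueError("columns must be the 8 canonical categories in order")
        if (df.values < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", df.astype(int))

    @classmethod
    def from_long(cls, long_df: pd.DataFrame) -> "SpectrumTable":
        """Build from long-format rows (category, strain, glucose, count)."""
        bad = set(long_df["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        wide = (long_df.pivot_table(index=["strain", "glucose"],
                                    columns="category", values="count",
                                    aggfunc="sum", fill_value=0)
                .reindex(columns=CATEGORIES, fill_value=0))
        wide.columns.name = None
        return cls(wide)


@dataclass(frozen=True)
class ModelTestResult:
    term: str
    lr_stat: float
    df: int
    p: float
    model: str = ""
    note: str = ""


@dataclass(frozen=True)
class MultinomialFit:
    loglik: float
    coef: np.ndarray  # (n_predictors, n_categories - 1), baseline first category
    terms: tuple
    converged: bool
    separation: bool
    n_iter: int


def tabulate_spectrum(calls_table: pd.DataFrame) -> SpectrumTable:
    """Tabulate categorized calls into the 8-category spectrum.

    ``none_detected`` isolates are excluded; each remaining row must carry
    one canonical category.
    """
    df = calls_table[calls_table["category"] != "none_detected"]
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    long_df = (df.groupby(["strain", "glucose", "category"], observed=True)
               .size().reset_index(name="count"))
    return SpectrumTable.from_long(long_df)


def relative_frequencies(table: SpectrumTable) -> pd.DataFrame:
    """Per-condition category frequencies (rows sum to 1).

    Conditions with zero categorized isolates get NaN frequencies.
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.where(totals > 0), axis=0)
    return freqs


def _design(conditions: pd.MultiIndex, terms: tuple) -> np.ndarray:
    strains = conditions.get_level_values("strain")
    glucoses = conditions.get_level_values("glucose")
    s = (strains != strains[0]).astype(float)
    g = (glucoses != glucoses[0]).astype(float)
    cols = [np.ones(len(conditions))]
    for term in terms:
        if term == "glucose":
            cols.append(np.asarray(g))
        elif term == "strain":
            cols.append(np.asarray(s))
        elif term == "interaction":
            cols.append(np.asarray(g) * np.asarray(s))
        else:
            raise ValueError(f"unknown term {term!r}")
    return np.column_stack(cols)


_COEF_CAP = 30.0  # keeps separated fits finite; exp(-30) ~ 1e-13 in the ll


def _fit_grouped_multinomial(x: np.ndarray, y: np.ndarray,
                             tol: float = 1e-8, max_iter: int = 500) -> MultinomialFit:
    """Newton ascent for the grouped baseline-category logit.

    x: (n_conditions, p) design; y: (n_conditions, J) category counts.
    Category 0 is the baseline; coef has shape (p, J-1).
    """
    n, p = x.shape
    J = y.shape[1]
    beta = np.zeros((p, J - 1))
    totals = y.sum(axis=1)

    def loglik_and_probs(b):
        eta = np.concatenate([np.zeros((n, 1)), x @ b], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        expeta = np.exp(eta)
        pi = expeta / expeta.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.where(y > 0, y * np.log(pi), 0.0).sum())
        return ll, pi

    ll, pi = loglik_and_probs(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resid = y[:, 1:] - totals[:, None] * pi[:, 1:]
        grad = (x.T @ resid).ravel(order="F")
        # Hessian blocks H[j,k] = -sum_i N_i x_i x_i^T (pi_ij d_jk - pi_ij pi_ik)
        H = np.zeros((p * (J - 1), p * (J - 1)))
        for j in range(J - 1):
            for k in range(J - 1):
                w = totals * (pi[:, j + 1] * ((j == k) - pi[:, k + 1]))
                H[j * p:(j + 1) * p, k * p:(k + 1) * p] = -(x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        new_beta = beta + step.reshape((p, J - 1), order="F")
        np.clip(new_beta, -_COEF_CAP, _COEF_CAP, out=new_beta)
        new_ll, new_pi = loglik_and_probs(new_beta)
        # step halving if the full Newton step overshoots
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step.reshape((p, J - 1), order="F")
            np.clip(new_beta, -_COEF_CAP, _COEF_CAP, out=new_beta)
            new_ll, new_pi = loglik_and_probs(new_beta)
            halvings += 1
        delta = new_ll - ll
        beta, ll, pi = new_beta, new_ll, new_pi
        if abs(delta) < tol:
            break
    separation = bool(np.any(np.abs(beta) >= _COEF_CAP - 1e-6))
    converged = abs(delta) < tol
    return MultinomialFit(loglik=ll, coef=beta, terms=(), converged=converged,
                          separation=separation, n_iter=n_iter)


def fit_multinomial(table: SpectrumTable, terms: tuple = ()) -> MultinomialFit:
    """Fit a baseline-category multinomial logit on the grouped counts.

    ``terms`` is a subset of ("glucose", "strain", "interaction"); an
    intercept is always included.  Baseline category is AT>GC (first in
    canonical order); likelihood-ratio tests do not depend on this choice.
    """
    counts = table.counts
    if (counts.sum(axis=0) > 0).sum() < 2:
        raise ValueError("need at least 2 observed categories")
    x = _design(counts.index, tuple(terms))
    fit = _fit_grouped_multinomial(x, counts.values.astype(float))
    return MultinomialFit(loglik=fit.loglik, coef=fit.coef, terms=tuple(terms),
                          converged=fit.converged, separation=fit.separation,
                          n_iter=fit.n_iter)


def type2_tests_multinomial(table: SpectrumTable) -> list[ModelTestResult]:
    """Type-II likelihood-ratio tests for glucose, strain and interaction.

    Main effects are tested by dropping each from the additive model
    (marginality principle); the interaction by dropping it from the full
    model.  With 8 categories each binary term has 7 df.
    """
    J = len(CATEGORIES)
    df_term = J - 1
    fits = {
        "additive": fit_multinomial(table, ("glucose", "strain")),
        "glucose_only": fit_multinomial(table, ("glucose",)),
        "strain_only": fit_multinomial(table, ("strain",)),
        "full": fit_multinomial(table, ("glucose", "strain", "interaction")),
    }
    notes = {name: "separation" if f.separation else ""
             for name, f in fits.items()}
    results = []
    for term, big, small in (("glucose", "additive", "strain_only"),
                             ("strain", "additive", "glucose_only"),
                             ("interaction", "full", "additive")):
        lr = max(0.0, 2.0 * (fits[big].loglik - fits[small].loglik))
        note = "; ".join(filter(None, {notes[big], notes[small]}))
        results.append(ModelTestResult(term=term, lr_stat=lr, df=df_term,
                                       p=chisq_sf(lr, df_term),
                                       model="multinomial", note=note))
    return results


def fit_binomial_class(table: SpectrumTable, category: str) -> list[ModelTestResult]:
    """Type-II LR tests for one category vs all others (binomial logit).

    Each term (glucose, strain, interaction) is tested with 1 df.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    counts = table.counts
    hits = counts[category].values.astype(float)
    totals = counts.sum(axis=1).values.astype(float)
    if hits.sum() == 0:
        return [ModelTestResult(term=t, lr_stat=float("nan"), df=1,
                                p=float("nan"), model=f"binomial:{category}",
                                note="category never observed")
                for t in ("glucose", "strain", "interaction")]
    y = np.column_stack([hits, totals - hits])
    flags: set[str] = set()

    def ll(terms):
        x = _design(counts.index, terms)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            flags.add("separation")
        return float(res.llf)

    ll_add = ll(("glucose", "strain"))
    ll_g = ll(("glucose",))
    ll_s = ll(("strain",))
    ll_full = ll(("glucose", "strain", "interaction"))
    note = "; ".join(sorted(flags))
    out = []
    for term, big, small in (("glucose", ll_add, ll_s),
                             ("strain", ll_add, ll_g),
                             ("interaction", ll_full, ll_add)):
        lr = max(0.0, 2.0 * (big - small))
        out.append(ModelTestResult(term=term, lr_stat=lr, df=1,
                                   p=chisq_sf(lr, 1),
                                   model=f"binomial:{category}", note=note))
    return out
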