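"""Reporting layer: model selection, class labeling, transitions, associations.

Turns fitted latent class / latent transition models into the analysis
artifacts an epidemiologist reports: a fit-statistics table across candidate
numbers of classes, nested likelihood-ratio tests, labeled item-response
class profiles, cross-phase transition tables, and logistic-regression
associations between modal class membership and self-reported comorbidities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from . import lca
from .containers import IndicatorMatrix
from .errors import ConfigurationError, FitError, ValidationError
from .lca import LCAFit, LCAParams

#: Caveat attached to chi-square p-values for K vs K+1 comparisons: the
#: smaller model sits on the boundary of the larger model's parameter space,
#: so the usual chi-square regularity conditions do not strictly hold.
BOUNDARY_CAVEAT = (
    "chi-square reference distribution; mixture-boundary conditions violate "
    "the usual regularity assumptions for comparisons of K vs K+1 classes"
)

#: Default mapping from medication category to the disease group it primarily
#: treats; used to compose class labels.  User-editable.
DEFAULT_DISEASE_MAP: dict[str, str] = {
    "ACEi": "HTN/CVD",
    "ARB": "HTN/CVD",
    "beta_blocker": "HTN/CVD",
    "calcium_channel_blocker": "HTN/CVD",
    "diuretic": "HTN/CVD",
    "antiplatelet": "HTN/CVD",
    "anticoagulant": "HTN/CVD",
    "nitrate": "HTN/CVD",
    "antiarrhythmic": "HTN/CVD",
    "biguanide": "T2D",
    "sulfonylurea": "T2D",
    "insulin": "T2D",
    "other_diabetes_med": "T2D",
    "statin": "Hychol",
    "other_lipid_lowering": "Hychol",
}

#: Fixed priority order in which disease groups appear in a composed label.
DISEASE_PRIORITY: tuple[str, ...] = ("HTN/CVD", "T2D", "Hychol")


@dataclass(frozen=True)
class SelectionTable:
    """Fit statistics for a range of candidate class counts."""

    table: pd.DataFrame  # one row per K
    fits: dict[int, LCAFit] = field(repr=False, default_factory=dict)

    def best_bic(self) -> int:
        """K minimizing BIC among converged fits."""
        ok = self.table[self.table["converged"]]
        if ok.empty:
            raise FitError("no converged fits in the selection table")
        return int(ok.loc[ok["bic"].idxmin(), "n_classes"])


@dataclass(frozen=True)
class ClassProfile:
    """One latent class with threshold-labeled items and a composed name."""

    class_index: int
    prevalence: float
    response: pd.Series  # per-item response probability
    high_items: tuple[str, ...]  # response > high threshold
    moderate_items: tuple[str, ...]  # between the thresholds, inclusive
    low_items: tuple[str, ...]  # response < low threshold
    label: str


@dataclass(frozen=True)
class TransitionTable:
    """K x K cross-phase counts and row percentages."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame  # 100 * count / row total, 2 decimals

    @property
    def n_subjects(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class NestedLRTResult:
    """Likelihood-ratio comparison of a K-class vs (K+1)-class model."""

    g2_delta: float
    df_delta: int
    p_value: float
    caveat: str = BOUNDARY_CAVEAT


def fit_range(
    data: IndicatorMatrix,
    k_min: int = 2,
    k_max: int = 8,
    *,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> SelectionTable:
    """Fit every K in [k_min, k_max] and tabulate the fit statistics.

    Per-K fitting failures are recorded as non-converged rows with NaN
    statistics instead of aborting the sweep.
    """
    if k_min < 1 or k_max < k_min:
        raise ValidationError("need 1 <= k_min <= k_max")
    rows = []
    fits: dict[int, LCAFit] = {}
    for k in range(k_min, k_max + 1):
        try:
            f = lca.fit_lca(
                data, k, n_starts=n_starts, seed=seed + k, tol=tol,
                max_iter=max_iter,
            )
        except FitError as exc:
            warnings.warn(f"K={k}: {exc}", stacklevel=2)
            rows.append(
                {
                    "n_classes": k,
                    "g_squared": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "caic": np.nan,
                    "sabic": np.nan,
                    "entropy": np.nan,
                    "n_params": lca.count_params(k, data.n_items),
                    "converged": False,
                }
            )
            continue
        fits[k] = f
        rows.append(
            {
                "n_classes": k,
                "g_squared": f.g_squared,
                "aic": f.aic,
                "bic": f.bic,
                "caic": f.caic,
                "sabic": f.sabic,
                "entropy": f.entropy,
                "n_params": f.n_params,
                "converged": f.converged,
            }
        )
    return SelectionTable(table=pd.DataFrame(rows), fits=fits)


def lrt_nested(fit_small: LCAFit, fit_large: LCAFit) -> NestedLRTResult:
    """Deviance-difference test of K classes against K+1 on the same data.

    G^2_delta = G^2_small - G^2_large;  df_delta = J + 1 (one extra
    prevalence plus J extra item-response probabilities).
    """
    if fit_large.n_classes != fit_small.n_classes + 1:
        raise ValidationError(
            f"expected K_large = K_small + 1, got {fit_small.n_classes} vs "
            f"{fit_large.n_classes}"
        )
    if fit_small.params.n_items != fit_large.params.n_items:
        raise ValidationError("fits come from data with different items")
    if fit_small.posteriors.shape[0] != fit_large.posteriors.shape[0]:
        raise ValidationError("fits come from data with different subjects")
    g2_delta = fit_small.g_squared - fit_large.g_squared
    df_delta = fit_large.n_params - fit_small.n_params
    if g2_delta < -1e-6 * (1.0 + abs(fit_large.g_squared)):
        raise FitError(
            "larger model has higher deviance beyond tolerance; a fit has "
            "likely stopped in a poor local optimum"
        )
    g2_delta = max(g2_delta, 0.0)
    return NestedLRTResult(
        g2_delta=float(g2_delta),
        df_delta=int(df_delta),
        p_value=float(chi2.sf(g2_delta, df_delta)),
    )


def _compose_label(
    response: pd.Series,
    disease_map: dict[str, str],
    low_floor: float,
    low_thresh: float,
) -> str:
    if (response < low_floor).all():
        return "Low medication"
    diseases = []
    for disease in DISEASE_PRIORITY:
        items = [i for i, d in disease_map.items() if d == disease]
        if any(response.get(i, 0.0) >= low_thresh for i in items):
            diseases.append(disease)
    for disease in sorted(set(disease_map.values())):
        if disease not in DISEASE_PRIORITY and any(
            response.get(i, 0.0) >= low_thresh
            for i, d in disease_map.items()
            if d == disease
        ):
            diseases.append(disease)
    if not diseases:
        return "Other medication"
    return "+".join(diseases) + " predominant"


def label_classes(
    params: LCAParams,
    item_names: tuple[str, ...] | list[str],
    *,
    high_thresh: float = 0.7,
    low_thresh: float = 0.3,
    low_medication_floor: float = 0.06,
    disease_map: dict[str, str] | None = None,
) -> list[ClassProfile]:
    """Partition each class's items by response probability and name the class.

    An item is "high" if its response probability is strictly above
    ``high_thresh``, "low" if strictly below ``low_thresh``, and "moderate"
    in the closed band between them (a probability of exactly 0.7 is
    moderate).  A class whose every item sits below ``low_medication_floor``
    is labeled "Low medication"; otherwise the label is composed from the
    disease groups of its high/moderate items in fixed priority order
    (HTN/CVD, then T2D, then Hychol).
    """
    if not (0.0 < low_thresh < high_thresh < 1.0):
        raise ConfigurationError("need 0 < low_thresh < high_thresh < 1")
    if disease_map is None:
        disease_map = DEFAULT_DISEASE_MAP
    if not disease_map:
        raise ConfigurationError("disease_map must not be empty")
    item_names = [str(n) for n in item_names]
    if len(item_names) != params.n_items:
        raise ValidationError(
            f"{len(item_names)} item names for J={params.n_items} items"
        )
    profiles = []
    for c in range(params.n_classes):
        resp = pd.Series(params.item_response[c], index=item_names)
        high = tuple(resp.index[resp > high_thresh])
        low = tuple(resp.index[resp < low_thresh])
        moderate = tuple(
            resp.index[(resp >= low_thresh) & (resp <= high_thresh)]
        )
        profiles.append(
            ClassProfile(
                class_index=c,
                prevalence=float(params.class_prevalence[c]),
                response=resp,
                high_items=high,
                moderate_items=moderate,
                low_items=low,
                label=_compose_label(
                    resp, disease_map, low_medication_floor, low_thresh
                ),
            )
        )
    return profiles


def transition_table(
    classes_p1: np.ndarray,
    classes_p2: np.ndarray,
    labels: list[str] | None = None,
    n_classes: int | None = None,
) -> TransitionTable:
    """Cross-tabulate phase-1 by phase-2 modal classes.

    Row percentages are 100 * count / row total, rounded to 2 decimals;
    an all-zero row reports 0.00 throughout.
    """
    c1 = np.asarray(classes_p1)
    c2 = np.asarray(classes_p2)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValidationError(
            f"class vectors must be aligned 1-d arrays, got {c1.shape} vs {c2.shape}"
        )
    k = n_classes or int(max(c1.max(), c2.max())) + 1
    if labels is None:
        labels = [f"LC{c}" for c in range(k)]
    if len(labels) != k:
        raise ValidationError(f"{len(labels)} labels for {k} classes")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (c1, c2), 1)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_tot > 0, 100.0 * counts / row_tot, 0.0)
    idx = pd.Index(labels, name="phase1")
    cols = pd.Index(labels, name="phase2")
    return TransitionTable(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        row_percent=pd.DataFrame(np.round(pct, 2), index=idx, columns=cols),
    )


def comorbidity_association(
    classes: np.ndarray,
    flags: pd.DataFrame,
    *,
    reference: int | None = None,
) -> pd.DataFrame:
    """Logistic regression of each comorbidity flag on modal class membership.

    Each comorbidity is regressed on class-indicator dummies (reference =
    largest class unless given); odds ratios carry Wald 95% confidence
    intervals.  Classes in which the flag is constant (all 0 or all 1) cause
    complete separation: the affected odds ratios are flagged and reported as
    +/- infinity with NaN intervals rather than from a diverging fit.

    Returns a tidy DataFrame with one row per (comorbidity, non-reference
    class).
    """
    classes = np.asarray(classes)
    if classes.ndim != 1 or len(classes) != len(flags):
        raise ValidationError("classes and flags must be aligned per subject")
    levels = np.unique(classes)
    if reference is None:
        counts = pd.Series(classes).value_counts()
        reference = int(counts.idxmax())
    if reference not in levels:
        raise ValidationError(f"reference class {reference} not present")
    others = [int(c) for c in levels if c != reference]
    x = np.column_stack([(classes == c).astype(float) for c in others])
    x = sm.add_constant(x, has_constant="add")
    rows = []
    for name in flags.columns:
        y = flags[name].to_numpy(dtype=float)
        if not np.isin(y, (0, 1)).all():
            raise ValidationError(f"flag column {name!r} must be binary")
        # A class where the flag is constant separates perfectly from the
        # intercept-only direction; detect it up front.
        sep_classes = {
            int(c)
            for c in levels
            if y[classes == c].min() == y[classes == c].max()
        }
        separated = bool(sep_classes)
        or_est = ci_lo = ci_hi = pvals = None
        if not separated:
            try:
                res = sm.Logit(y, x).fit(disp=0, maxiter=200, tol=1e-8)
                if not res.mle_retvals.get("converged", False):
                    separated = True
                else:
                    or_est = np.exp(res.params[1:])
                    ci = res.conf_int(alpha=0.05)
                    ci_lo = np.exp(ci[1:, 0])
                    ci_hi = np.exp(ci[1:, 1])
                    pvals = res.pvalues[1:]
            except Exception:  # perfect separation raises from statsmodels
                separated = True
        for pos, c in enumerate(others):
            if separated:
                p1 = y[classes == c].mean()
                p0 = y[classes == reference].mean()
                inf_or = np.inf if p1 >= p0 else 0.0
                rows.append(
                    {
                        "comorbidity": name,
                        "class": c,
                        "reference": reference,
                        "odds_ratio": inf_or if c in sep_classes or reference in sep_classes else np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "separated": True,
                    }
                )
            else:
                rows.append(
                    {
                        "comorbidity": name,
                        "class": c,
                        "reference": reference,
                        "odds_ratio": float(or_est[pos]),
                        "ci_low": float(ci_lo[pos]),
                        "ci_high": float(ci_hi[pos]),
                        "p_value": float(pvals[pos]),
                        "separated": False,
                    }
                )
    return pd.DataFrame(rows)


def plot_response_heatmap(
    profiles_by_phase: dict[str, list[ClassProfile]], path: str
) -> None:
    """Item x class heat map of response probabilities, one panel per phase."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phases = list(profiles_by_phase)
    fig, axes = plt.subplots(
        1, len(phases), figsize=(4.0 * len(phases) + 2.0, 8.0), squeeze=False
    )
    for ax, phase in zip(axes[0], phases):
        profiles = profiles_by_phase[phase]
        mat = np.column_stack([p.response.to_numpy() for p in profiles])
        im = ax.imshow(mat, aspect="auto", vmin=0, vmax=1, cmap="YlOrRd")
        ax.set_xticks(range(len(profiles)))
        ax.set_xticklabels(
            [f"LC{p.class_index}" for p in profiles], rotation=45, ha="right"
        )
        ax.set_yticks(range(len(profiles[0].response)))
        ax.set_yticklabels(profiles[0].response.index, fontsize=6)
        ax.set_title(phase)
    fig.colorbar(im, ax=axes[0].tolist(), label="item-response probability")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
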