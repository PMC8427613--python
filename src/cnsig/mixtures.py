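"""Per-feature finite mixture models and sum-of-posterior encoding.

Continuous features (segsize, copynumber, changepoint) are modeled as
univariate Gaussian mixtures; count features (bp10MB, bpchrarm, osCN) as
Poisson mixtures. For each feature the cohort's pooled events are fitted
by EM over a range of component counts k, the number of components chosen
by BIC, and each sample is then encoded as the vector of summed posterior
component memberships of its events — the sample-by-component matrix the
signature factorization consumes. Row sums per feature equal the sample's
event count for that feature, so the encoding conserves event mass.

The cohort-level mixture model is frozen after fitting on a reference
cohort and reused verbatim to encode validation cohorts, so external
samples are expressed in the same component space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln, logsumexp

from .features import CONTINUOUS_FEATURES, FEATURE_NAMES, FeatureEvents, pooled_values

__all__ = [
    "Mixture",
    "ComponentModel",
    "FeatureMixtureModel",
    "MixtureResult",
    "fit_mixture",
    "fit_component_model",
    "posterior_encode",
]


@dataclass
class Mixture:
    """A fitted univariate mixture: family, weights and per-component params.

    ``params`` rows are (mean, sd) for gaussian, (rate,) for poisson;
    components are sorted by location ascending.
    """

    family: str
    weights: np.ndarray
    params: np.ndarray
    log_likelihood: float = np.nan
    n_obs: int = 0
    selection_trace: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.weights)

    def component_loglik(self, x: np.ndarray) -> np.ndarray:
        """n x k matrix of log p(x | component)."""
        x = np.asarray(x, dtype=float)[:, None]
        if self.family == "gaussian":
            mu = self.params[:, 0][None, :]
            sd = self.params[:, 1][None, :]
            return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2
        if self.family == "poisson":
            lam = self.params[:, 0][None, :]
            if (x < 0).any():
                raise ValueError("negative value outside Poisson support")
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = x * np.log(lam) - lam - gammaln(x + 1)
            # rate exactly 0: pmf is a point mass at 0
            ll = np.where((lam == 0) & (x == 0), 0.0, ll)
            ll = np.where((lam == 0) & (x > 0), -np.inf, ll)
            return ll
        raise ValueError(f"unknown family {self.family}")

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """n x k matrix of P(component | x); rows sum to 1."""
        logw = np.log(np.maximum(self.weights, 1e-300))[None, :]
        joint = self.component_loglik(x) + logw
        return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))

    def bic(self) -> float:
        p = 3 * self.k - 1 if self.family == "gaussian" else 2 * self.k - 1
        return -2.0 * self.log_likelihood + p * np.log(max(self.n_obs, 1))


def _em_once(
    x: np.ndarray,
    family: str,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> Mixture:
    n = len(x)
    # weighted EM over unique values: count features collapse to a handful
    # of atoms, which makes the E-step effectively O(k * n_unique)
    xu, cnt = np.unique(x, return_counts=True)
    cw = cnt.astype(float)
    if len(xu) > 1024:
        # continuous data: collapse to <=1024 weighted atoms (bin means);
        # bin width is far below any admissible component sd
        edges = np.linspace(xu[0], xu[-1], 1025)
        idx = np.clip(np.digitize(xu, edges) - 1, 0, 1023)
        mass = np.bincount(idx, weights=cw, minlength=1024)
        sums = np.bincount(idx, weights=cw * xu, minlength=1024)
        keep = mass > 0
        xu = sums[keep] / mass[keep]
        cw = mass[keep]

    weights = np.full(k, 1.0 / k)
    if family == "gaussian":
        means = rng.choice(x, size=k, replace=n < k)
        sd = max(np.std(x), sd_floor)
        params = np.column_stack([means, np.full(k, sd)])
    else:
        qs = rng.uniform(0.05, 0.95, size=k)
        params = np.quantile(x, np.sort(qs))[:, None] + rng.uniform(0, 0.5, size=(k, 1))

    model = Mixture(family=family, weights=weights, params=params, n_obs=n)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logw = np.log(np.maximum(model.weights, 1e-300))[None, :]
        joint = model.component_loglik(xu) + logw
        norm = logsumexp(joint, axis=1)
        ll = float((cw * norm).sum())
        resp = np.exp(joint - norm[:, None]) * cw[:, None]
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        weights = nk / n
        if family == "gaussian":
            mu = (resp * xu[:, None]).sum(axis=0) / nk
            var = (resp * (xu[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.maximum(np.sqrt(var), sd_floor)
            params = np.column_stack([mu, sd])
        else:
            lam = (resp * xu[:, None]).sum(axis=0) / nk
            params = lam[:, None]
        model = Mixture(family=family, weights=weights, params=params,
                        log_likelihood=ll, n_obs=n)
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            break
        prev_ll = ll
    order = np.argsort(model.params[:, 0], kind="stable")
    model.weights = model.weights[order]
    model.params = model.params[order]
    return model


def fit_mixture(
    values,
    family: str,
    k_range=range(1, 11),
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    weight_floor: float = 1e-3,
) -> Mixture:
    """EM fit over ``k_range`` with random restarts; k selected by BIC.

    Components degenerating to negligible weight (or a Gaussian sd pinned
    at the variance floor) are pruned and the model refitted at reduced k.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need >= 10 values to fit a mixture, got {len(x)}")
    if family == "poisson" and (x < 0).any():
        raise ValueError("negative values are outside the Poisson support")
    rng = np.random.default_rng(seed)
    span = float(np.ptp(x))
    sd_floor = max(1e-6 * span, 1e-9)

    trace: dict[int, float] = {}
    best: Mixture | None = None
    k_max_eff = min(max(k_range), max(len(np.unique(x)), 1))
    for k in k_range:
        if k > k_max_eff:
            break
        cand: Mixture | None = None
        for _ in range(n_init):
            try:
                m = _em_once(x, family, k, rng, tol, max_iter, sd_floor)
            except FloatingPointError:
                continue
            if not np.isfinite(m.log_likelihood):
                continue
            if cand is None or m.log_likelihood > cand.log_likelihood:
                cand = m
        if cand is None:
            continue
        trace[k] = cand.bic()
        if best is None or trace[k] < best.bic():
            best = cand
    if best is None:
        raise RuntimeError(f"EM failed to converge for any k in {list(k_range)}; trace={trace}")

    # prune degenerate components, refit at reduced k
    while best.k > 1:
        degenerate = best.weights < weight_floor
        if best.family == "gaussian":
            degenerate |= best.params[:, 1] <= sd_floor
        if not degenerate.any():
            break
        k_new = int((~degenerate).sum())
        refit = None
        for _ in range(n_init):
            m = _em_once(x, family, max(k_new, 1), rng, tol, max_iter, sd_floor)
            if refit is None or m.log_likelihood > refit.log_likelihood:
                refit = m
        best = refit
    best.selection_trace = trace
    return best


FAMILY_BY_FEATURE = {f: ("gaussian" if f in CONTINUOUS_FEATURES else "poisson")
                     for f in FEATURE_NAMES}


@dataclass
class ComponentModel:
    """Frozen cohort-level mixtures for all six features."""

    mixtures: dict[str, Mixture]

    @property
    def component_labels(self) -> list[str]:
        return [f"{feat}:{i + 1}"
                for feat in FEATURE_NAMES
                for i in range(self.mixtures[feat].k)]

    @property
    def n_components(self) -> int:
        return sum(self.mixtures[f].k for f in FEATURE_NAMES)

    def to_dict(self) -> dict:
        return {
            feat: {
                "family": m.family,
                "weights": [float(w) for w in m.weights],
                "params": [[float(v) for v in row] for row in m.params],
                "log_likelihood": float(m.log_likelihood),
                "n_obs": int(m.n_obs),
                "selection_trace": {int(k): float(v) for k, v in m.selection_trace.items()},
            }
            for feat, m in self.mixtures.items()
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ComponentModel":
        mixtures = {}
        for feat, d in doc.items():
            mixtures[feat] = Mixture(
                family=d["family"],
                weights=np.array(d["weights"], dtype=float),
                params=np.array(d["params"], dtype=float),
                log_likelihood=float(d["log_likelihood"]),
                n_obs=int(d["n_obs"]),
                selection_trace={int(k): float(v) for k, v in d["selection_trace"].items()},
            )
        return cls(mixtures=mixtures)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ComponentModel":
        path = str(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(doc)


class FeatureMixtureModel:
    """Model object: pooled cohort feature events -> per-feature mixtures.

    ``fit`` returns a :class:`MixtureResult` wrapping the frozen
    :class:`ComponentModel` plus the encoded sample-by-component matrix.
    """

    def __init__(self, cohort: list[FeatureEvents],
                 families: dict[str, str] | None = None):
        self.cohort = cohort
        self.families = dict(FAMILY_BY_FEATURE, **(families or {}))

    def fit(self, k_range=range(1, 11), n_init: int = 5, tol: float = 1e-6,
            max_iter: int = 1000, seed: int = 0) -> "MixtureResult":
        import warnings

        mixtures = {}
        for i, feat in enumerate(FEATURE_NAMES):
            values = pooled_values(self.cohort, feat)
            family = self.families[feat]
            if len(values) < 10:
                # sparse feature (e.g. a quiet low-resolution cohort with no
                # change points): degenerate single-component fallback
                warnings.warn(
                    f"feature {feat}: only {len(values)} pooled events; "
                    "using a single-component fallback mixture", stacklevel=2)
                loc = float(np.mean(values)) if len(values) else 0.0
                scale = float(np.std(values)) if len(values) > 1 else 0.0
                params = (np.array([[loc, max(scale, 1e-6)]])
                          if family == "gaussian" else np.array([[max(loc, 0.0)]]))
                mixtures[feat] = Mixture(family=family, weights=np.array([1.0]),
                                         params=params, n_obs=len(values))
                continue
            mixtures[feat] = fit_mixture(
                values, family, k_range=k_range, n_init=n_init,
                tol=tol, max_iter=max_iter, seed=seed * 1009 + i,
            )
        model = ComponentModel(mixtures=mixtures)
        matrix = posterior_encode(self.cohort, model)
        return MixtureResult(model=model, matrix=matrix)


@dataclass
class MixtureResult:
    model: ComponentModel
    matrix: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Feature mixtures: {self.model.n_components} components over "
                 f"{len(FEATURE_NAMES)} features, {len(self.matrix)} samples", ""]
        for feat in FEATURE_NAMES:
            m = self.model.mixtures[feat]
            locs = ", ".join(f"{p[0]:.4g}" for p in m.params)
            lines.append(f"  {feat:<12} {m.family:<8} k={m.k:<3} locations: {locs}")
        return "\n".join(lines)


def fit_component_model(cohort: list[FeatureEvents], seed: int = 0,
                        **kwargs) -> ComponentModel:
    """Functional wrapper: fit all six feature mixtures on a cohort."""
    return FeatureMixtureModel(cohort).fit(seed=seed, **kwargs).model


def posterior_encode(cohort: list[FeatureEvents], model: ComponentModel) -> pd.DataFrame:
    """Encode samples as summed posterior component memberships.

    Entry (sample, component c of feature f) = sum over the sample's events
    of feature f of P(component = c | event value). The row block for one
    feature sums to the sample's event count for that feature.
    """
    missing = [f for f in FEATURE_NAMES if f not in model.mixtures]
    if missing:
        raise ValueError(f"component model missing features: {missing}")
    labels = model.component_labels
    rows = np.zeros((len(cohort), len(labels)))
    col = 0
    for feat in FEATURE_NAMES:
        m = model.mixtures[feat]
        for si, fe in enumerate(cohort):
            vals = np.asarray(fe.events[feat], dtype=float)
            if vals.size:
                rows[si, col:col + m.k] = m.posterior(vals).sum(axis=0)
        col += m.k
    return pd.DataFrame(rows, index=[fe.sample_id for fe in cohort], columns=labels)
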