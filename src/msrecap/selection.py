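"""AIC ranking, Akaike weights and model averaging.

AIC = deviance + 2k.  Because every candidate's deviance carries the same
(omitted) saturated-model constant, differences and weights are unaffected
by that constant.  Model-averaged parameters use weights renormalised over
the models above a weight threshold, and the unconditional standard error
is the Burnham-Anderson sum  SE = sum_i w_i * sqrt(var_i + (theta_i -
theta_bar)^2), which folds between-model spread into the reported error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ModelRecord:
    """Lightweight (name, deviance, k) entry, e.g. a published table row."""

    name: str
    deviance: float
    free_parameters: int


@dataclass
class ModelSet:
    """Candidate models ranked by AIC."""

    models: list
    table: pd.DataFrame
    averaging_threshold: float = 0.02

    def __len__(self):
        return len(self.models)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _name_of(m, i):
    name = getattr(m, "name", "") or ""
    if not name and hasattr(m, "spec"):
        name = m.spec.notation()
    return name or f"model_{i}"


def rank(models, averaging_threshold: float = 0.02) -> ModelSet:
    """Rank fitted models (or plain records) by AIC.

    Entries are sorted by ascending ΔAIC with ties broken by fewer
    parameters; weights are exp(-ΔAIC/2), normalised over the full set.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    sizes = {getattr(m, "dataset_size", None) for m in models}
    sizes.discard(None)
    if len(sizes) > 1:
        raise ValueError("models were fitted to different datasets")

    dev = np.array([float(m.deviance) for m in models])
    k = np.array([int(m.free_parameters) for m in models])
    aic = dev + 2.0 * k
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    order = sorted(range(len(models)), key=lambda i: (delta[i], k[i]))
    table = pd.DataFrame(
        {
            "model": [_name_of(models[i], i) for i in order],
            "deviance": dev[order],
            "parameters": k[order],
            "AIC": aic[order],
            "dAIC": delta[order],
            "weight": w[order],
        }
    )
    return ModelSet(
        models=[models[i] for i in order],
        table=table.reset_index(drop=True),
        averaging_threshold=averaging_threshold,
    )


def model_average(model_set: ModelSet, parameter_selector, threshold: float | None = None):
    """Model-averaged estimate and unconditional SE of one parameter.

    ``parameter_selector`` is either a callable ``model -> (estimate, se)``
    or a ``(family, axes_dict)`` pair passed to ``FittedModel.estimate``.
    Models with Akaike weight above the threshold (default: the set's
    ``averaging_threshold``) are retained and their weights renormalised.
    """
    if threshold is None:
        threshold = model_set.averaging_threshold
    weights = model_set.table["weight"].to_numpy()
    keep = weights > threshold
    if not keep.any():
        raise ValueError("no model above the averaging threshold")
    w = weights[keep] / weights[keep].sum()

    if callable(parameter_selector):
        pairs = [parameter_selector(m) for m, k_ in zip(model_set.models, keep) if k_]
    else:
        family, axes = parameter_selector
        pairs = [
            m.estimate(family, **axes) for m, k_ in zip(model_set.models, keep) if k_
        ]
    est = np.array([p[0] for p in pairs], dtype=float)
    se = np.array([p[1] for p in pairs], dtype=float)
    if np.any(np.isnan(est)):
        raise ValueError("parameter missing from a retained model")
    avg = float(w @ est)
    unc = float(np.sum(w * np.sqrt(se**2 + (est - avg) ** 2)))
    return avg, unc
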