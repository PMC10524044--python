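"""Small serialization helpers shared by the pipeline and CLI."""

from __future__ import annotations

import numpy as np

from .er import ERModelFit


def fit_to_dict(fit: ERModelFit) -> dict:
    """JSON-serializable report of a fitted exposure-response model."""
    return {
        "family": fit.family,
        "metric": fit.metric,
        "transform": fit.transform,
        "log_base": fit.log_base,
        "coefficients": dict(zip(fit.exog_names, np.asarray(fit.params).tolist())),
        "se": {k: float(v) for k, v in fit.bse.items()},
        "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
        "thresholds": None if fit.thresholds is None else np.asarray(fit.thresholds).tolist(),
        "deviance": float(fit.deviance),
        "converged": bool(fit.converged),
        "notes": list(fit.notes),
    }
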