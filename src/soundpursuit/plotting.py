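"""Quick-look plots: measured-vs-predicted overlays and transfer characteristics."""

from __future__ import annotations

import numpy as np

from .identify import TrialFit, predict_response
from .lti import frequency_response
from .simulate import TrialRecord


def plot_trial_overlay(trial: TrialRecord, fit: TrialFit, ax=None):
    """Overlay stimulus, measured head trace and model prediction for one trial."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    pred = predict_response(fit.params, trial.stimulus)
    t = trial.stimulus.time
    ax.plot(t, trial.stimulus.position, "k-", lw=0.8, label="stimulus")
    ax.plot(t, trial.head.position, lw=0.8, label="head")
    ax.plot(t, pred.position, lw=1.6, alpha=0.7, label="model")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("azimuth (deg)")
    ax.set_title(
        f"{trial.subject_id} trial {trial.trial_number}: "
        f"f_C={fit.params.f_c:.2f} Hz, Q={fit.params.q:.2f}, r2={fit.r2:.2f}"
    )
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_transfer(fits: list[TrialFit], f_max: float = 1.5, ax=None):
    """Fitted gain characteristics of a session, colour-coded by trial number."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    f = np.linspace(1e-3, f_max, 400)
    cmap = plt.get_cmap("viridis")
    for i, fit in enumerate(fits):
        fr = frequency_response(fit.params, f)
        ax.plot(f, fr.gain, color=cmap(i / max(len(fits) - 1, 1)), lw=0.8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("gain")
    return ax
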