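"""Simple Kaplan-Meier step plots for selected pairs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt
from lifelines import KaplanMeierFitter

from .io import ClinicalTable
from .screen import PairResult

__all__ = ["plot_km_pair"]


def plot_km_pair(pair: PairResult, clinical: ClinicalTable, ax=None):
    """KM curves of Group 1 (correlated) vs Group 2 for one pair."""
    if pair.partition is None:
        raise ValueError("pair has no partition")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    times = clinical.times()
    events = clinical.events()
    lab = pair.partition.labels()
    for mask, name in ((lab, "Group 1 (correlated)"), (~lab, "Group 2")):
        kmf = KaplanMeierFitter(label=f"{name} (n={int(mask.sum())})")
        kmf.fit(times[mask], event_observed=events[mask])
        kmf.plot_survival_function(ax=ax, ci_show=False)
    title = f"{pair.mir_id} / {pair.gene_id}"
    if pair.logrank is not None:
        title += f"  log-rank p={pair.logrank.p:.2e}"
    ax.set_title(title)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    return ax
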