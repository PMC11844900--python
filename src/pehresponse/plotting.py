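"""Per-participant responder plot: HDI intervals against the ROPE band."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .responder import ResponderCall, ResponderLabel, RopeInterval

_LABEL_COLORS = {
    ResponderLabel.HYPOTENSIVE_RESPONDER: "tab:blue",
    ResponderLabel.HYPERTENSIVE_RESPONDER: "tab:red",
    ResponderLabel.NON_RESPONDER: "tab:gray",
    ResponderLabel.UNDECIDED: "tab:orange",
}


def responder_plot(
    calls: list[ResponderCall],
    rope: RopeInterval,
    title: Optional[str] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Plot each participant's delta with its HDI as an error bar, ordered by
    delta, with the ROPE band as vertical dotted lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(calls))))
    ordered = sorted(calls, key=lambda c: c.delta)
    for y, call in enumerate(ordered):
        color = _LABEL_COLORS[call.label]
        ax.errorbar(
            call.delta,
            y,
            xerr=[[call.delta - call.hdi.lower], [call.hdi.upper - call.delta]],
            fmt="o",
            color=color,
            ecolor=color,
            capsize=2,
        )
    ax.axvline(rope.lower, linestyle=":", color="black")
    ax.axvline(rope.upper, linestyle=":", color="black")
    ax.axvline(0.0, linestyle="-", color="black", linewidth=0.5)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([c.participant_id for c in ordered], fontsize=7)
    ax.set_xlabel("post-exercise change (mmHg)")
    if title:
        ax.set_title(title)
    return ax
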