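"""Annotated force-displacement plots."""

from __future__ import annotations


def plot_compression_results(results, ax=None):
    """Plot the truncated trace with the stiffness regression line and the
    yield, maximum and failure loads marked.

    Returns the matplotlib axes.  Imports matplotlib lazily so the analysis
    stack stays importable in minimal environments.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    curve = results.truncated
    m = results.mech
    r = m.elastic_region
    d, f = curve.displacement, curve.force

    ax.plot(d, f, color="0.25", lw=1.0, label="recorded force")
    # stiffness regression line over the elastic region
    seg = d[r.start_index:r.end_index + 1]
    ax.plot(seg, r.intercept + r.slope * seg, color="tab:blue", lw=2.0,
            label=f"S = {m.stiffness:.1f} N/mm")
    for idx, load, label, color in (
            (m.yield_index, m.yield_load, f"yL = {m.yield_load:.1f} N", "tab:orange"),
            (m.max_index, m.max_load, f"Fmax = {m.max_load:.1f} N", "tab:red"),
            (m.failure_index, m.failure_load, f"fL = {m.failure_load:.1f} N", "tab:purple")):
        ax.plot(d[idx], load, "o", color=color, ms=6, label=label)
    ax.set_xlabel("displacement (mm)")
    ax.set_ylabel("force (N)")
    title = m.specimen_id + (f" [{m.group_label}]" if m.group_label else "")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    return ax
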