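"""Static trend report plot."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analytics import FluorSeries, TrendVerdict, _normalize_to_initial  # noqa: E402


def plot_trend(
    series: FluorSeries,
    verdict: Optional[TrendVerdict] = None,
    path: Union[str, Path, None] = None,
):
    """Two-panel normalized OD / fluorescence-index plot; optionally saved."""
    fig, (ax_od, ax_fl) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    ax_od.plot(series.times_h, _normalize_to_initial(series.od_values),
               color="tab:blue")
    ax_od.set_ylabel("normalized OD")
    ax_fl.plot(series.times_h, _normalize_to_initial(series.index_values),
               color="tab:green")
    ax_fl.set_ylabel("normalized fluorescence index")
    ax_fl.set_xlabel("time (h)")
    title = f"LED {series.led_id}"
    if verdict is not None:
        title += f" — verdict: {verdict.label}"
        if verdict.onset_h is not None:
            for ax in (ax_od, ax_fl):
                ax.axvline(verdict.onset_h, color="tab:red", ls="--", lw=1)
    fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
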