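"""Optional headless-safe plots; CSV/JSON remain the canonical outputs."""

from __future__ import annotations

from pathlib import Path


def plot_sweep(frames, path: Path) -> None:
    """Effect vs elimination threshold for both sweep directions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for frame in frames:
        direction = frame["direction"].iloc[0]
        ax.plot(frame["threshold"], frame["effect_kcal"], ".", alpha=0.4)
        ax.plot(frame["threshold"], frame["smoothed_effect"], label=direction)
    ax.invert_xaxis()
    ax.set_xlabel("elimination threshold on |unaccounted energy| (kcal/day)")
    ax.set_ylabel("diet effect, low minus high (kcal/day)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sensitivity(table, path: Path) -> None:
    """Diet effect and per-10% effect across the nonadherence grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["p"] * 100, table["effect_kcal"], "o-", label="effect (kcal/day)")
    ax.plot(
        table["p"] * 100,
        table["effect_per_10pct"],
        "s--",
        label="per 10% carbohydrate",
    )
    ax.set_xlabel("assumed nonadherence (% of energy)")
    ax.set_ylabel("kcal/day")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
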