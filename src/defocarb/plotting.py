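"""Quick-look plots for curve and map objects."""

from __future__ import annotations


def plot_sensitivity_curve(curve, ax=None):
    """Rainfall sensitivity a (per level) with the significant range marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = curve.table
    ax.plot(t["level"], t["a"] * 100, color="0.4", lw=1.5,
            label="a*100 (all windows)")
    sig = t[t["significant"]]
    ax.plot(sig["level"], sig["a"] * 100, "o", color="C0", ms=4,
            label=f"significant (P < {curve.alpha:g})")
    ax.set_xlabel("window-center MAP (mm yr$^{-1}$)")
    ax.set_ylabel("AGB sensitivity (Mg C ha$^{-1}$ / 100 mm yr$^{-1}$)")
    ax.legend(frameon=False)
    return ax


def plot_field(field, ax=None, **kwargs):
    """pcolormesh of a lat/lon field with its units on the colorbar."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = ax.pcolormesh(field.lon, field.lat, field.values, **kwargs)
    plt.colorbar(m, ax=ax, label=field.attrs.get("units", ""))
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
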