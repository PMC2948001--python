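"""Optional diagnostic plots (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np


def plot_variance_function(varfun, ax=None):
    """Bin points and the smoothed pooled-variance curve for one group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = np.linspace(varfun.bin_centers[0] - 0.5, varfun.bin_centers[-1] + 0.5, 400)
    ax.plot(a, varfun(a), label="smoothed $\\sigma^2(A)$")
    ax.plot(varfun.bin_centers, varfun.bin_variances, "o", ms=3, label="bin medians")
    ax.set_xlabel("mean log2 intensity $A$")
    ax.set_ylabel("pooled variance")
    ax.set_title(f"LPE baseline variance ({varfun.condition})")
    ax.legend()
    return ax


def plot_threshold_path(path_table, best_delta=None, ax=None):
    """CV accuracy and surviving gene count along the shrinkage path."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(path_table["delta"], path_table["accuracy"], "-o", ms=3)
    if best_delta is not None:
        ax.axvline(best_delta, ls="--", color="grey", label=f"best $\\Delta$={best_delta:.2f}")
        ax.legend()
    ax.set_xlabel("shrinkage $\\Delta$")
    ax.set_ylabel("CV accuracy (%)")
    ax2 = ax.twinx()
    ax2.plot(path_table["delta"], path_table["n_genes"], color="tab:orange", alpha=0.6)
    ax2.set_yscale("symlog")
    ax2.set_ylabel("genes with nonzero offset")
    return ax
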