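"""Environmentally regulated expression (EReX) as per-gene regression residuals.

EReX is defined as the residual of an ordinary least-squares fit of observed
expression on imputed GReX, gene by gene, with intercept.  It captures the
expression variability not explained by the cis-genetic component —
environmental effects plus any unmodeled (e.g. trans-genetic) variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_erex"]


def compute_erex(
    observed: np.ndarray, grex: np.ndarray, gene_ids=None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-gene OLS residuals of observed expression on GReX.

    Returns the EReX matrix (same shape as the inputs) and a per-gene fit
    summary with slope, intercept, fraction of variance explained and a
    ``degenerate`` flag.  Genes with zero-variance GReX cannot be regressed;
    they get centered observed values as EReX and are flagged.
    """
    observed = np.asarray(observed, dtype=float)
    grex = np.asarray(grex, dtype=float)
    if observed.shape != grex.shape:
        raise ValueError(f"shape mismatch: observed {observed.shape} vs grex {grex.shape}")
    n, G = observed.shape
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(G)]
    if len(gene_ids) != G:
        raise ValueError("gene_ids length does not match matrices")

    erex = np.empty_like(observed)
    rows = []
    for j in range(G):
        y = observed[:, j]
        x = grex[:, j]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0.0:
            resid = y - y.mean()
            erex[:, j] = resid
            rows.append((gene_ids[j], 0.0, float(y.mean()), 0.0, True))
            continue
        slope = float(xc @ (y - y.mean())) / sxx
        intercept = float(y.mean() - slope * x.mean())
        fitted = intercept + slope * x
        resid = y - fitted
        erex[:, j] = resid
        var_y = float(np.var(y))
        r2 = 0.0 if var_y == 0 else float(np.var(fitted) / var_y)
        rows.append((gene_ids[j], slope, intercept, r2, False))
    summary = pd.DataFrame(
        rows, columns=["gene", "slope", "intercept", "var_explained", "degenerate"]
    )
    return erex, summary
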