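"""Model-comparison report: BIC deviations and fit correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd


def compare_models(fits: dict, records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Compare fitted models on the same dataset.

    ``fits`` maps a model name (e.g. "leg0", "leg4", "leg4R2", "LACT",
    "MT") to a fitted estimator.  Returns a table with the BIC, the BIC
    deviation from the best (smallest) value, and the Pearson correlation
    between observed and fitted phenotypes.  Models fitted to different
    record counts (other than LACT/MT, which rephrase the phenotypes)
    raise: BIC comparisons are only meaningful on the same records.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_td = {name: m.n_records_ for name, m in fits.items()
            if type(m).__name__ == "RandomRegressionModel"
            or type(m).__name__ == "ReducedRankRandomRegression"}
    if len(set(n_td.values())) > 1:
        raise ValueError(f"models fitted on different record counts: {n_td}")
    rows = []
    for name, m in fits.items():
        rho = m.score(records) if records is not None else np.nan
        rows.append((name, m.bic(), rho, m.n_records_, m.converged_))
    table = pd.DataFrame(rows, columns=["model", "bic", "rho", "n_records",
                                        "converged"]).set_index("model")
    # BIC deviations are reported within groups of models sharing the same
    # phenotypes (same record count); LACT/MT rephrase the data and are
    # compared by rho only.
    table["delta_bic"] = table.groupby("n_records")["bic"].transform(
        lambda b: b - b.min())
    return table[["bic", "delta_bic", "rho", "n_records", "converged"]]
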