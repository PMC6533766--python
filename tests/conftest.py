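import numpy as np
import pandas as pd
import pytest

from methdyn.panel import AmpliconPanel, write_panel_table
from methdyn.simdata import make_toy_panel, write_reference


@pytest.fixture(scope="session")
def toy_panel():
    """Three random ~240 bp amplicons (top/bottom/top) on one contig."""
    panel, contig = make_toy_panel(n_amplicons=3, length=240, gap=30, seed=7)
    return panel, contig


@pytest.fixture(scope="session")
def toy_panel_files(toy_panel, tmp_path_factory):
    panel, contig = toy_panel
    d = tmp_path_factory.mktemp("panel")
    fasta = d / "ref.fa"
    table = d / "panel.tsv"
    write_reference(contig, panel.amplicons[0].chrom, fasta)
    write_panel_table(panel, table)
    return table, fasta


def gls_time_fit(df: pd.DataFrame, sigma_u2: float, sigma_e2: float):
    """Closed-form GLS fit of the categorical-time model with known
    variance components (independent oracle for the mixed-model Wald test).

    Returns (beta, cov_beta, chi2 over time coefficients).
    """
    d = df.sort_values(["subject", "time_h"]).reset_index(drop=True)
    times = sorted(d["time_h"].unique())
    X = np.column_stack(
        [np.ones(len(d))]
        + [(d["time_h"] == t).to_numpy(float) for t in times[1:]]
    )
    y = d["level"].to_numpy(float)
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    for _, g in d.groupby("subject"):
        idx = g.index.to_numpy()
        n = len(idx)
        V = sigma_e2 * np.eye(n) + sigma_u2 * np.ones((n, n))
        Vi = np.linalg.inv(V)
        Xg, yg = X[idx], y[idx]
        XtViX += Xg.T @ Vi @ Xg
        XtViy += Xg.T @ Vi @ yg
    cov = np.linalg.inv(XtViX)
    beta = cov @ XtViy
    b = beta[1:]
    chi2 = float(b @ np.linalg.solve(cov[1:, 1:], b))
    return beta, cov, chi2


def balanced_series(
    n_subjects: int,
    times,
    deltas: dict,
    baseline: float = 50.0,
    subject_sd: float = 3.0,
    residual_sd: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced random-intercept time-course data with known effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0.0, subject_sd)
        for t in times:
            lvl = baseline + u + deltas.get(t, 0.0) + rng.normal(0.0, residual_sd)
            rows.append((f"s{i:03d}", float(t), lvl))
    return pd.DataFrame(rows, columns=["subject", "time_h", "level"])
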