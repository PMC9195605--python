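"""Shared fixtures: the worked-example panel, printed reference tables, and
independent brute-force oracles for the multirule and bracketed-risk checks.

The oracles deliberately re-derive rule logic from first principles (plain
loops over the stated rule definitions) so they share no code path with the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm

import labqcplan as lq
from labqcplan import datasets


# ---------------------------------------------------------------------------
# reference data


@pytest.fixture(scope="session")
def panel():
    return datasets.example_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {p.name: p for p in panel}


@pytest.fixture(scope="session")
def published_run_sizes():
    return datasets.published_run_size_matrix()


@pytest.fixture(scope="session")
def published_ma():
    return datasets.published_ma_summaries()


@pytest.fixture(scope="session")
def candidates():
    return list(lq.CANDIDATE_PROCEDURES.values())


# ---------------------------------------------------------------------------
# brute-force multirule oracle


def naive_reject(procedure: lq.SQCProcedure, z) -> bool:
    """Literal reading of the rule definitions, checked rule by rule."""
    z = list(z)
    n = len(z)
    for rule in procedure.sub_rules:
        if rule.kind == "limit":
            if any(abs(v) > rule.k for v in z):
                return True
        elif rule.kind == "two_of_three_2s":
            for s in range(n - 2):
                w = z[s : s + 3]
                if sum(v > 2 for v in w) >= 2 or sum(v < -2 for v in w) >= 2:
                    return True
        elif rule.kind == "three_of_three_1s":
            for s in range(n - 2):
                w = z[s : s + 3]
                if all(v > 1 for v in w) or all(v < -1 for v in w):
                    return True
        elif rule.kind == "six_x_one_side":
            for s in range(n - 5):
                w = z[s : s + 6]
                if all(v > 0 for v in w) or all(v < 0 for v in w):
                    return True
    return False


@pytest.fixture(scope="session")
def rule_oracle():
    return naive_reject


# ---------------------------------------------------------------------------
# discrete-event bracketed E(Nuf) oracle


def simulate_bracketed_nuf(
    procedure: lq.SQCProcedure,
    sigma: float,
    se: float,
    n: int,
    n_replicates: int,
    seed: int,
) -> tuple[float, float]:
    """Event-level simulation of the bracketed process.

    Per replicate: QC events with all controls shifted by ``se`` are drawn
    until one rejects (evaluated by the brute-force rule oracle); every
    accepted run releases ``n`` patient results, each unreliable with the
    normal-tail defect probability at quality ``sigma``.  Returns the mean
    excess (over baseline) number of unreliable final results and its
    standard error.
    """
    rng = np.random.default_rng(seed)
    p_err = norm.cdf(se - sigma) + norm.cdf(-se - sigma)
    p_base = 2 * norm.cdf(-sigma)
    totals = np.empty(n_replicates)
    for r in range(n_replicates):
        accepted = 0
        while True:
            z = rng.normal(se, 1.0, procedure.n_controls)
            if naive_reject(procedure, z):
                break
            accepted += 1
        released = accepted * n
        totals[r] = rng.binomial(released, p_err) - rng.binomial(released, p_base)
    return float(totals.mean()), float(totals.std(ddof=1) / np.sqrt(n_replicates))


@pytest.fixture(scope="session")
def bracketed_oracle():
    return simulate_bracketed_nuf


def flat_profile(sigma: float, tea: float = 10.0, daily_volume: int = 50):
    """Profile with three identical levels at the requested sigma (< 6)."""
    cv = tea / (sigma + 1.0)  # bias chosen so (tea - bias)/cv == sigma
    bias = tea - sigma * cv
    level = lq.QCLevel(target=100.0, tea_percent=tea, bias_percent=bias, cv_percent=cv)
    return lq.AnalyteProfile(
        name=f"sigma{sigma}", unit="", levels=(level, level, level),
        daily_volume=daily_volume,
    )


@pytest.fixture(scope="session")
def make_flat_profile():
    return flat_profile
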