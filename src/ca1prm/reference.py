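"""The shipped reference weight set and its regeneration.

The model's published weight tables are not redistributable, so the
package ships its own reference set: a hand-tuned anchor found by
constrained search.  The theta loop (PYR->PYR, PYR->BiC, BiC->PYR) was
designed from the linear stability analysis — the PYR+BiC equilibrium
is placed just below PYR saturation so that the Hopf root falls in the
theta band with a small critical delay — and the remaining six weights
were selected by randomized search so that the full circuit passes the
primary and secondary constraints, the subsystem frequencies fall in
their bands, and the CCK perturbation protocols behave as expected.

:func:`make_reference_set` re-validates the anchor from scratch and is
deterministic: regenerating with the shipped seed reproduces the
fixture byte-for-byte.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParams, WeightSet
from .simulate import SimConfig
from .ga import GAConfig, evaluate_constraints, mutate, _baseline_metrics

__all__ = ["REFERENCE_WEIGHTS", "reference_weights", "make_reference_set",
           "REFERENCE_SEED"]

REFERENCE_SEED = 2025

#: Hand-tuned anchor ("SRC->TGT": weight, au).  Inhibitory weights are
#: stored with their sign.
REFERENCE_WEIGHTS = {
    "PYR->PYR": 0.073684210526,
    "PYR->BiC": 0.042731708802,
    "PYR->PV": 0.01065,
    "BiC->PYR": -0.027657505681,
    "PV->PYR": -0.05708,
    "CCK->CCK": -0.04117,
    "PV->CCK": -0.01729,
    "CCK->PV": -0.03984,
    "PV->PV": -0.01493,
}


def reference_weights() -> WeightSet:
    """The shipped reference weight set."""
    return WeightSet(dict(REFERENCE_WEIGHTS))


def make_reference_set(seed: int = REFERENCE_SEED,
                       params: ModelParams | None = None,
                       sim_config: SimConfig | None = None,
                       max_attempts: int = 2000):
    """Regenerate the reference set with provenance.

    Starts from the hand-tuned anchor, validates the full constraint
    battery (primary against the candidate's own baseline powers, so
    the power fractions are identically 1, plus the secondary removal
    constraint).  If the anchor itself passes — it does for the shipped
    parameters — it is returned after 0 mutation steps; otherwise a
    seeded mutate-and-test search runs until a passing set is found.

    Returns ``(WeightSet, provenance_dict)``.
    """
    params = params or ModelParams()
    sim_config = sim_config or SimConfig()
    config = GAConfig(seed=seed)
    rng = np.random.default_rng(seed)
    candidate = reference_weights()
    evaluations = 0
    while True:
        summary, _ = _baseline_metrics(candidate, params, sim_config)
        own_reference = (summary.theta_power, summary.gamma_power)
        report = evaluate_constraints(candidate, own_reference, params,
                                      config, sim_config)
        evaluations += 1
        if report.overall_pass:
            break
        if evaluations >= max_attempts:
            raise RuntimeError(
                "reference-set search failed after "
                f"{max_attempts} attempts; last failures: "
                f"{', '.join(report.failing())}")
        candidate = mutate(reference_weights(), rng, config)
    provenance = {
        "seed": seed,
        "evaluations": evaluations,
        "constraints": report.to_dict(),
        "baseline_powers": {"theta": own_reference[0],
                            "gamma": own_reference[1]},
    }
    return candidate, provenance
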