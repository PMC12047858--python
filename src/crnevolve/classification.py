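"""Post-hoc oscillator classification, repair and pruning.

A network counts as a sustained oscillator when the Jacobian at a steady
state has an eigenvalue with positive real part and nonzero imaginary part
(an unstable focus, suggesting a limit cycle) and the steady-state
concentrations are positive. Networks passing the eigenvalue test but with
a non-positive steady-state concentration are *flagged* and may be repaired
by deleting a single reaction. Pruning greedily removes every reaction not
needed to keep the oscillator verdict.

Strictly positive real parts exclude conservative centers such as the
Lotka-Volterra system, whose eigenvalues are purely imaginary; the
``center_tolerance`` mode relaxes the real-part test to Re >= -1e-6 so such
neutrally stable oscillators classify as oscillators too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .network import ReactionNetwork
from .simulation import compile_network, eigenvalues, steady_state

__all__ = ["ClassificationConfig", "ClassificationResult", "classify", "repair", "prune"]


@dataclass(frozen=True)
class ClassificationConfig:
    re_tol: float = 1e-9           # strict mode: need Re > re_tol
    im_tol: float = 1e-9           # need |Im| > im_tol
    center_tolerance: bool = False  # relaxed mode: need Re >= -center_re_tol
    center_re_tol: float = 1e-6
    steady_state_horizon: float = 50.0

    @property
    def re_threshold(self) -> float:
        return -self.center_re_tol if self.center_tolerance else self.re_tol


@dataclass
class ClassificationResult:
    verdict: str  # oscillator | flagged | non_oscillator | undetermined
    steady_state: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    repaired_network: ReactionNetwork | None = None


def classify(
    net: ReactionNetwork, cfg: ClassificationConfig = ClassificationConfig()
) -> ClassificationResult:
    """Eigenvalue-based oscillator verdict at a located steady state.

    * ``oscillator``: some eigenvalue has Re above the threshold and
      |Im| > im_tol, and every steady-state concentration of the recurrent
      species is strictly positive;
    * ``flagged``: the eigenvalue test passes but some concentration is
      non-positive;
    * ``undetermined``: no steady state could be located;
    * ``non_oscillator``: otherwise.
    """
    ss = steady_state(net, t_horizon=cfg.steady_state_horizon)
    if ss is None:
        return ClassificationResult(verdict="undetermined")
    compiled = compile_network(net)
    eig = eigenvalues(compiled.jac(ss))
    eig_ok = bool(
        np.any((eig.real > cfg.re_threshold) & (np.abs(eig.imag) > cfg.im_tol))
    )
    dyn = ~compiled.sink_species()
    positive = bool(np.all(ss[dyn] > 0.0)) if np.any(dyn) else False
    if eig_ok and positive:
        verdict = "oscillator"
    elif eig_ok:
        verdict = "flagged"
    else:
        verdict = "non_oscillator"
    return ClassificationResult(verdict=verdict, steady_state=ss, eigenvalues=eig)


def repair(
    net: ReactionNetwork, cfg: ClassificationConfig = ClassificationConfig()
) -> ClassificationResult:
    """Single-deletion repair of a flagged network.

    Tries deactivating each active reaction in list order; the first
    variant that classifies as an oscillator is returned (with
    ``repaired_network`` set). If none works the flagged result stands.
    """
    base = classify(net, cfg)
    if base.verdict != "flagged":
        return base
    for i, r in enumerate(net.reactions):
        if not r.active:
            continue
        variant = net.copy()
        variant.reactions[i] = dc_replace(r, active=False)
        res = classify(variant, cfg)
        if res.verdict == "oscillator":
            res.repaired_network = variant
            return res
    return base


def prune(
    net: ReactionNetwork, cfg: ClassificationConfig = ClassificationConfig()
) -> ReactionNetwork:
    """Strip reactions not needed for oscillation.

    Requires the input to classify as an oscillator. Repeatedly deactivates
    the first active reaction (in list order) whose removal preserves the
    oscillator verdict, until no reaction can be removed. The result always
    classifies as an oscillator.
    """
    if classify(net, cfg).verdict != "oscillator":
        raise ValueError("prune requires a network that classifies as an oscillator")
    current = net.copy()
    changed = True
    while changed:
        changed = False
        for i, r in enumerate(current.reactions):
            if not r.active:
                continue
            variant = current.copy()
            variant.reactions[i] = dc_replace(r, active=False)
            if classify(variant, cfg).verdict == "oscillator":
                current = variant
                changed = True
                break
    return current
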