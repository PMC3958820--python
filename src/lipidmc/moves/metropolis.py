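"""The Metropolis acceptance rule with Jacobian correction.

A trial move m -> n is accepted with probability

    min{1, p_sel(n->m)/p_sel(m->n) * exp(-beta dH) * J(n)/J(m)}

where dH = dE for structural moves, and
dH = dE + P dV - n_molecules kT ln(V'/V) for volume moves (center-of-mass
scaling convention with a uniform-in-ln V proposal).  Infeasible proposals
are always rejected but count as attempts.
"""

from __future__ import annotations

import logging

import numpy as np

from ..constants import ATM_A3_TO_KCAL_MOL, KB
from .proposals import MoveProposal

logger = logging.getLogger(__name__)


def metropolis_accept(
    proposal: MoveProposal,
    temperature: float,
    rng: np.random.Generator,
    pressure: float = 1.0,
    n_molecules: int | None = None,
    include_jacobian: bool = True,
) -> bool:
    """Accept/reject a proposal.  ``pressure`` in atm, ``temperature`` in K.

    ``include_jacobian=False`` deliberately omits the volume-element
    correction (for demonstrating the resulting sampling bias); production
    runs always include it.
    """
    if not proposal.feasible:
        return False
    if not np.isfinite(proposal.delta_E):
        logger.warning(
            "non-finite energy delta in %s move; rejected", proposal.move_class
        )
        return False
    beta = 1.0 / (KB * temperature)
    dh = proposal.delta_E
    arg_extra = 0.0
    if proposal.move_class == "volume":
        if n_molecules is None:
            raise ValueError("volume move needs n_molecules")
        dh += pressure * proposal.delta_V * ATM_A3_TO_KCAL_MOL
        arg_extra = n_molecules * proposal.log_volume_ratio
    jac = proposal.jacobian_ratio if include_jacobian else 1.0
    log_p = -beta * dh + arg_extra
    # accept without drawing when the bound exceeds 1
    factor = proposal.selection_ratio * jac
    if log_p >= 0 and factor >= 1.0:
        return True
    p = factor * np.exp(min(log_p, 700.0))
    return bool(rng.random() < p)
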