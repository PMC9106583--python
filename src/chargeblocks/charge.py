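"""Phospho-aware residue charge model and sliding-window charge profiles.

The charge rule is the fixed integer assignment used throughout the
package: Arg and Lys +1, Asp and Glu -1, phospho-Ser and phospho-Thr -2,
everything else (including His by default) 0.  No pH dependence is
modelled; at physiological pH the phosphate group carries roughly two
negative charges, which is what the -2 encodes.

A charge profile is the sum of residue charges in a window of ``W``
residues centred on each position.  At the termini the window is truncated
to the sequence (no padding), so a value exists for every residue; the
per-position effective window length is retained so that per-residue mean
charge (sum / effective length) can be derived exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .sequences import AnnotatedSequence

State = Literal["interphase", "mitotic"]


class ChargeError(ValueError):
    """Invalid charge-model usage."""


@dataclass(frozen=True)
class ChargeModel:
    """Immutable residue -> integer charge assignment.

    Parameters
    ----------
    phospho_charge
        Charge of a phosphorylated S/T (default -2).
    histidine_charge
        Charge of His (default 0; the fixed-charge rule treats only
        R/K/D/E as charged).
    """

    positive: frozenset[str] = frozenset({"R", "K"})
    negative: frozenset[str] = frozenset({"D", "E"})
    phospho_charge: int = -2
    histidine_charge: int = 0

    def charge(self, residue: str, is_phosphorylated: bool = False) -> int:
        if is_phosphorylated:
            if residue not in ("S", "T"):
                raise ChargeError(
                    f"phospho flag on {residue!r}: only S/T can be phosphorylated"
                )
            return self.phospho_charge
        if residue in self.positive:
            return 1
        if residue in self.negative:
            return -1
        if residue == "H":
            return self.histidine_charge
        return 0

    def charge_array(self, seq: AnnotatedSequence) -> np.ndarray:
        """Per-residue integer charges honouring the phospho state."""
        q = np.zeros(len(seq), dtype=np.int64)
        for i, res in enumerate(seq.residues):
            if res in self.positive:
                q[i] = 1
            elif res in self.negative:
                q[i] = -1
            elif res == "H":
                q[i] = self.histidine_charge
        for pos in seq.phosphorylated:
            res = seq.residues[pos - 1]
            q[pos - 1] = self.phospho_charge if res in ("S", "T") else 0
        return q


DEFAULT_MODEL = ChargeModel()


def residue_charge(
    residue: str, is_phosphorylated: bool = False, model: ChargeModel = DEFAULT_MODEL
) -> int:
    """Charge of a single residue under the model (see :class:`ChargeModel`)."""
    return model.charge(residue, is_phosphorylated)


def set_state(seq: AnnotatedSequence, state: State) -> AnnotatedSequence:
    """Apply a cell-cycle phospho state to a sequence.

    ``mitotic`` phosphorylates every annotated site (hyperphosphorylated
    form); ``interphase`` dephosphorylates all of them.  Idempotent.
    """
    if state == "mitotic":
        return seq.replace(phosphorylated=seq.phosphosites)
    if state == "interphase":
        return seq.replace(phosphorylated=frozenset())
    raise ChargeError(f"unknown state {state!r}; expected 'interphase' or 'mitotic'")


def _resolve_state(seq: AnnotatedSequence, state: State | None) -> AnnotatedSequence:
    return seq if state is None else set_state(seq, state)


def net_charge(
    seq: AnnotatedSequence,
    state: State | None = None,
    model: ChargeModel = DEFAULT_MODEL,
) -> int:
    """Sum of residue charges over the full sequence in the given state."""
    return int(model.charge_array(_resolve_state(seq, state)).sum())


@dataclass(frozen=True)
class ChargeProfile:
    """Windowed charge values for one sequence in one phospho state.

    ``sums[i]`` is the sum of charges over the (truncated) window centred
    at 1-based position ``i+1``; ``coverage[i]`` is the number of residues
    that window actually covers, so ``means = sums / coverage`` is the
    per-residue mean charge used by the block-designation rule.
    """

    sequence_id: str
    state: str
    window: int
    residues: str
    charges: np.ndarray = field(repr=False)
    sums: np.ndarray = field(repr=False)
    coverage: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.sums)

    @property
    def means(self) -> np.ndarray:
        return self.sums / self.coverage

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "residue": list(self.residues),
                "charge": self.charges,
                "windowed_sum": self.sums,
                "windowed_mean": self.means,
            }
        )


def charge_profile(
    seq: AnnotatedSequence,
    window: int = 25,
    state: State | None = None,
    model: ChargeModel = DEFAULT_MODEL,
) -> ChargeProfile:
    """Sliding-window charge profile at an odd window size.

    The value at position ``i`` sums charges over positions
    ``[i-(W-1)/2, i+(W-1)/2]`` intersected with the sequence.
    """
    n = len(seq)
    if window % 2 == 0 or not 1 <= window <= n:
        raise ChargeError(
            f"window must be odd and within [1, {n}]; got {window}"
        )
    resolved = _resolve_state(seq, state)
    q = model.charge_array(resolved)
    kernel = np.ones(window, dtype=np.int64)
    sums = np.convolve(q, kernel, mode="same")
    coverage = np.convolve(np.ones(n, dtype=np.int64), kernel, mode="same")
    state_label = state if state is not None else (
        "mitotic" if resolved.phosphorylated else "custom"
    )
    return ChargeProfile(
        sequence_id=seq.id,
        state=state_label,
        window=window,
        residues=seq.residues,
        charges=q,
        sums=sums,
        coverage=coverage,
    )


def count_sp_sites(seq: AnnotatedSequence, sites: frozenset[int] | None = None) -> int:
    """Count annotated phosphosites matching the minimal CDK1 consensus S/T-P.

    The minimal cyclin-dependent-kinase-1 motif is a Ser or Thr immediately
    followed by Pro.  ``sites`` defaults to the sequence's annotated
    phosphosites.
    """
    positions = seq.phosphosites if sites is None else sites
    n = len(seq)
    count = 0
    for pos in positions:
        if seq.residues[pos - 1] in ("S", "T") and pos < n and seq.residues[pos] == "P":
            count += 1
    return count
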