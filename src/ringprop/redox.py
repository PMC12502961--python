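"""Vertical IP/EA and thermodynamic-cycle redox potentials.

With single-point energies of the three charge states (−1, 0, +1) at the
neutral geometry,

    IP  = E_gas(+1) − E_gas(0)          (vertical ionization potential, eV)
    EA  = E_gas(0)  − E_gas(−1)         (vertical electron affinity, eV;
                                         positive when the anion is bound)

and with aqueous Gibbs free energies G_aq the one-electron redox potentials
against the standard hydrogen electrode (absolute reference E_ref = 4.28 V)
follow the thermodynamic cycle

    E_ox  = [G_aq(+1) − G_aq(0)] / n − E_ref
    E_red = [G_aq(0) − G_aq(−1)] / n − E_ref ,

so a more stable anion gives a higher (less negative) E_red.  Energies are
stored per molecule in eV; the division by the Faraday constant is then the
identity map eV → V per electron, which keeps the unit algebra trivial.
Hartree inputs are converted at load (1 hartree = 27.211386 eV).

The module also provides the ordinary-least-squares property-pair
correlation (IP vs E_ox, EA vs E_red) used in the dataset-wide analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HARTREE_TO_EV = 27.211386

__all__ = [
    "GibbsSet",
    "ElectroConfig",
    "vertical_ip",
    "vertical_ea",
    "oxidation_potential",
    "reduction_potential",
    "linear_correlation",
    "read_gibbs_table",
    "HARTREE_TO_EV",
]


@dataclass
class GibbsSet:
    """Per-molecule state energies by charge (−1, 0, +1), in eV."""

    mol_id: str
    e_gas: dict[int, float] = field(default_factory=dict)
    g_aq: dict[int, float] = field(default_factory=dict)

    def _require(self, table: dict[int, float], charges: tuple[int, ...], what: str) -> None:
        missing = [q for q in charges if q not in table]
        if missing:
            raise ValueError(
                f"molecule {self.mol_id!r}: missing {what} energies for charge(s) {missing}"
            )
        bad = [q for q in charges if not np.isfinite(table[q])]
        if bad:
            raise ValueError(f"molecule {self.mol_id!r}: non-finite {what} energies at {bad}")


@dataclass(frozen=True)
class ElectroConfig:
    n_electrons: int = 1
    e_ref: float = 4.28  # V, absolute potential of the standard hydrogen electrode

    def validate(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


def vertical_ip(gibbs: GibbsSet) -> float:
    """IP = E_gas(+1) − E_gas(0), eV."""
    gibbs._require(gibbs.e_gas, (0, 1), "gas-phase")
    return gibbs.e_gas[1] - gibbs.e_gas[0]


def vertical_ea(gibbs: GibbsSet) -> float:
    """EA = E_gas(0) − E_gas(−1), eV (negative for an unbound anion)."""
    gibbs._require(gibbs.e_gas, (0, -1), "gas-phase")
    return gibbs.e_gas[0] - gibbs.e_gas[-1]


def oxidation_potential(gibbs: GibbsSet, cfg: ElectroConfig | None = None) -> float:
    """E_ox = [G_aq(+1) − G_aq(0)] / n − E_ref, volts."""
    cfg = cfg or ElectroConfig()
    cfg.validate()
    gibbs._require(gibbs.g_aq, (0, 1), "aqueous")
    return (gibbs.g_aq[1] - gibbs.g_aq[0]) / cfg.n_electrons - cfg.e_ref


def reduction_potential(gibbs: GibbsSet, cfg: ElectroConfig | None = None) -> float:
    """E_red = [G_aq(0) − G_aq(−1)] / n − E_ref, volts."""
    cfg = cfg or ElectroConfig()
    cfg.validate()
    gibbs._require(gibbs.g_aq, (0, -1), "aqueous")
    return (gibbs.g_aq[0] - gibbs.g_aq[-1]) / cfg.n_electrons - cfg.e_ref


def linear_correlation(x, y) -> tuple[float, float, float]:
    """Ordinary least squares fit y = slope·x + intercept.

    Returns (slope, intercept, R²) with R² the squared Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def read_gibbs_table(path) -> dict[str, GibbsSet]:
    """Load a long-format energy CSV: id, charge, phase {gas, aq}, energy, units.

    Hartree rows are converted to eV.  Returns GibbsSets keyed by molecule id.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "charge", "phase", "energy", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gibbs table {path} is missing columns: {sorted(missing)}")
    out: dict[str, GibbsSet] = {}
    for row in df.itertuples(index=False):
        units = str(row.units).lower()
        if units not in ("ev", "hartree"):
            raise ValueError(f"unknown energy units {row.units!r} for id {row.id!r}")
        energy = float(row.energy) * (HARTREE_TO_EV if units == "hartree" else 1.0)
        gs = out.setdefault(str(row.id), GibbsSet(mol_id=str(row.id)))
        phase = str(row.phase).lower()
        charge = int(row.charge)
        if phase == "gas":
            gs.e_gas[charge] = energy
        elif phase == "aq":
            gs.g_aq[charge] = energy
        else:
            raise ValueError(f"unknown phase {row.phase!r} for id {row.id!r}")
    return out
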