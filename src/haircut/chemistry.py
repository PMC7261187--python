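"""Droplet substrate-loading estimates.

Hairpin substrates are spiked into the single-cell master mix; when the
oil-water droplet forms, the mix is diluted two-fold. The expected number
of substrate molecules in a droplet is then

    (C / dilution) * V_drop * N_A

with C the master-mix molar concentration, V_drop the droplet volume in
liters (~270 pl for ~80 um droplets) and N_A Avogadro's number. Dividing
a droplet's aligned read count by this estimate gives the fraction of
loaded substrates recovered as sequenced molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "DropletParams",
    "molecules_per_droplet",
    "rounded_molecules_per_droplet",
    "recovery_fraction",
]

AVOGADRO = 6.02e23


@dataclass(frozen=True)
class DropletParams:
    """Droplet geometry and mixing constants.

    The stated droplet volume (270 pl) is used directly rather than
    recomputed from the 80 um diameter (a sphere of that diameter is
    ~268 pl); the diameter is retained as metadata.
    """

    diameter_um: float = 80.0
    volume_L: float = 270e-12
    master_mix_dilution: float = 2.0
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in ("diameter_um", "volume_L", "master_mix_dilution", "avogadro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def molecules_per_droplet(
    conc_nM: float, params: DropletParams = DropletParams()
) -> float:
    """Expected substrate molecules in one droplet at a master-mix
    concentration of ``conc_nM`` nanomolar."""
    if conc_nM < 0:
        raise ValueError("concentration must be >= 0")
    conc_molar = conc_nM * 1e-9
    return conc_molar / params.master_mix_dilution * params.volume_L * params.avogadro


def round_to_sig_figs(x: float, n_figs: int = 1) -> float:
    """Round to ``n_figs`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + n_figs - 1)


def rounded_molecules_per_droplet(
    conc_nM: float, params: DropletParams = DropletParams(), n_figs: int = 1
) -> float:
    """One-significant-figure molecule estimate, the precision at which
    per-drop loading is usually quoted."""
    return round_to_sig_figs(molecules_per_droplet(conc_nM, params), n_figs)


def recovery_fraction(
    aligned_reads_per_drop: Mapping[str, int],
    conc_nM: float,
    params: DropletParams = DropletParams(),
) -> dict[str, float]:
    """Per-droplet fraction of loaded substrates recovered as aligned reads."""
    if conc_nM <= 0:
        raise ValueError("concentration must be > 0 for recovery estimates")
    denom = molecules_per_droplet(conc_nM, params)
    return {cb: reads / denom for cb, reads in aligned_reads_per_drop.items()}
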