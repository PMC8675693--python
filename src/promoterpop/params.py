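"""Evolutionary constants shared across the tract, dating and simulation modules."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EvoParams:
    """Rates and times used throughout the analyses.

    Attributes
    ----------
    r : float
        Recombination rate per bp per generation. The default corresponds to
        3.3 cM/Mb, the local rate of the hotspot-flanked 18-kb promoter region.
    mu : float
        Mutation rate per site per year (0.5e-9 by default).
    g : float
        Generation time in years (29 by default).
    t_split_amh_ah : tuple of float
        Bracketing split times (years) between modern and archaic humans.
    t_split_nea_den : float
        Neanderthal-Denisovan split time in years.
    t_introgression : float
        Time of the archaic-into-modern introgression event in years.
    """

    r: float = 3.3e-8
    mu: float = 0.5e-9
    g: float = 29.0
    t_split_amh_ah: tuple[float, float] = (550_000.0, 765_000.0)
    t_split_nea_den: float = 450_000.0
    t_introgression: float = 50_000.0

    def __post_init__(self) -> None:
        for name in ("r", "mu", "g", "t_split_nea_den", "t_introgression"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.t_split_amh_ah
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("t_split_amh_ah must be a positive (low, high) pair")


DEFAULT_PARAMS = EvoParams()
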