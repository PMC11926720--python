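"""Exception hierarchy for domain errors."""


class NanonucError(Exception):
    """Base class for all package-specific errors."""


class CovolumeError(NanonucError, ValueError):
    """Molar volume at or inside the equation-of-state covolume."""


class SupercriticalError(NanonucError, ValueError):
    """Temperature at or above the critical temperature: no spinodal exists."""


class BeyondSpinodalError(NanonucError, ValueError):
    """Liquid pressure at or below the spinodal: metastability degree >= 1."""


class NoNucleationDriveError(NanonucError, ValueError):
    """Bubble internal pressure does not exceed the liquid pressure."""


class SuperStabilizedError(NanonucError, ValueError):
    """Elastic confinement removes all stationary points of the work curve."""


class ConvergenceError(NanonucError, RuntimeError):
    """Iterative solver failed to converge within its iteration budget."""


class GridError(NanonucError, ValueError):
    """Field grid too coarse for the requested wavelength."""


class ConfigError(NanonucError, ValueError):
    """Invalid or unknown keys in a configuration file."""
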