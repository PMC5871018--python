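"""Exception types shared across the package."""


class ImbalnetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ImbalnetError, ValueError):
    """Invalid or inconsistent model parameters."""


class BalanceInfeasibleError(ImbalnetError):
    """The balanced (large-network) solution does not exist.

    Raised when the mean-field connectivity matrix is singular so that no
    firing-rate vector can cancel the external drive -- it is impossible for
    the mean synaptic input to remain finite in the strong-coupling limit --
    or, for continuously indexed networks, when the external input is sharper
    than the recurrent kernels so the Fourier series of the balanced solution
    diverges.
    """


class DegenerateGeometryError(ImbalnetError):
    """Nullspace geometry makes the amplified-component formula undefined."""


class FitError(ImbalnetError):
    """A statistical fit failed or is unidentifiable."""
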