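"""Exception hierarchy for bvfit."""


class BvfitError(Exception):
    """Base class for all bvfit errors."""


class InvalidArgumentError(BvfitError, ValueError):
    """A numeric argument violates a precondition (e.g. non-positive b)."""


class MissingParameterError(BvfitError, KeyError):
    """A bond-type key could not be resolved in a ParameterSet."""

    def __init__(self, key):
        self.key = key
        super().__init__(f"no parameter for bond type {key}")

    def __str__(self):  # KeyError quotes its message by default
        return self.args[0]


class HeterolepticSiteError(BvfitError, ValueError):
    """An operation requiring a homoleptic site received a mixed-ligand one."""


class UnassignedOxidationError(BvfitError, ValueError):
    """An operation requiring an oxidation state received an unassigned site."""


class NoFeasibleShiftError(BvfitError, ValueError):
    """No single-parameter shift can bring the BVS to the oxidation state."""


class NoReferenceParameterError(BvfitError, KeyError):
    """A contact's element has no literature reference parameter."""


class ConvergenceError(BvfitError, RuntimeError):
    """The optimizer failed to reach the gradient tolerance.

    Carries the best-so-far state in ``best_result``.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class EmptyBondTypeError(BvfitError, RuntimeError):
    """A fitted bond type lost all of its supporting sites."""


class ConfigError(BvfitError, ValueError):
    """An invalid configuration value."""
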