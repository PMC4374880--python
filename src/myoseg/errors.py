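"""Exception hierarchy shared by all segmentation stages.

Every failure mode that the command-line interface maps to an exit code has
its own class so that callers can distinguish a bad input from a numerical
breakdown of an evolution.
"""


class MyosegError(Exception):
    """Base class for all package-specific errors."""


class InputError(MyosegError, ValueError):
    """Invalid user input: unreadable file, malformed mask, bad parameter."""


class EmptyRegionError(InputError):
    """An operation that needs at least one sample/pixel received none."""


class UndefinedMetricError(InputError):
    """A metric was requested on inputs for which it is undefined."""


class InitializationError(MyosegError, RuntimeError):
    """Automatic circle initialization failed.

    The known failure mode of Hough-based initialization: bright structures
    (fat, chest-wall muscle) can outvote the ventricular circles, or no
    concentric partner circle is found.
    """


class ContourCollapseError(MyosegError, RuntimeError):
    """One sign region of the level-set field vanished during evolution."""


class NumericInstabilityError(MyosegError, RuntimeError):
    """A level-set update produced non-finite values."""


class OneSidedWindowError(MyosegError, RuntimeError):
    """A local window does not straddle the contour.

    Raised by :func:`myoseg.local.local_means` / ``local_force``; the
    evolution loop catches it and skips the offending band point for the
    current iteration.
    """
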