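"""Exception hierarchy for the channel-analysis pipeline.

Each error corresponds to a distinct, user-actionable failure mode and maps
to its own CLI exit code (see :mod:`xtalchannels.cli`).
"""


class XtalChannelsError(Exception):
    """Base class for all package errors."""


class NoCrystalGeometryError(XtalChannelsError):
    """Input has no valid CRYST1 / cell+symmetry record."""


class EmptyStructureError(XtalChannelsError):
    """No atoms survive parsing (or selection)."""


class MemoryCapError(XtalChannelsError):
    """Padded atom set (or grid) exceeds the configured memory heuristic."""


class DegenerateInputError(XtalChannelsError):
    """Point set unusable for tetrahedralization (e.g. all coplanar)."""


class DegeneratePocketError(XtalChannelsError):
    """Pocket definition has no 3D convex hull (flat / too few atoms)."""


class BottleneckNotFoundError(XtalChannelsError):
    """BFS could not locate an edge realizing the requested bottleneck."""
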