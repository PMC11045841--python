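"""Exception hierarchy shared across the pipeline."""


class RotordynError(Exception):
    """Base class for all package errors."""


class ParseError(RotordynError):
    """Malformed trajectory input (bad XYZ frame, bad sidecar row)."""


class StructuralError(RotordynError):
    """Ensemble-level inconsistency (atom counts, time grids)."""


class UndefinedDihedralError(RotordynError):
    """Collinear atoms make the dihedral angle undefined."""


class ConfigurationError(RotordynError):
    """Missing or inconsistent configuration (dihedral map, run config)."""


class NoDecayError(RotordynError):
    """Trajectory has no S1->S0 transition."""


class EmptyPopulationError(RotordynError):
    """Statistics requested over zero classified trajectories."""


class FitFailureError(RotordynError):
    """Nonlinear fit did not converge from any starting point."""


class IntegrationError(RotordynError):
    """Surface-hopping integrator violated its energy tolerance."""
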