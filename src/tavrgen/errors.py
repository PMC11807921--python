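"""Exception hierarchy for tavrgen."""


class TavrgenError(Exception):
    """Base class for all tavrgen errors."""


class MeshError(TavrgenError):
    """Mesh construction or topology problem (e.g. non-watertight submesh)."""


class MeasurementError(TavrgenError):
    """A feature cannot be measured on the given mesh."""


class UnknownGroupError(TavrgenError):
    """A morph state references a PVA group the mesh does not define."""


class RangeError(TavrgenError):
    """Parameter range is invalid or a value lies outside it."""


class EmptyRangeError(RangeError):
    """Constraint rules left no admissible interval for a parameter."""


class CycleError(TavrgenError):
    """The parameter dependency graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "dependency cycle: " + " -> ".join(str(c) for c in self.cycle)
        )


class SchemaError(TavrgenError):
    """A patient file violates the JSON schema or format version."""


class GenerationError(TavrgenError):
    """The random patient generator exhausted its retry budget."""
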