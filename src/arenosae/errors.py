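"""Exception hierarchy shared across the toolkit."""


class ArenosaeError(Exception):
    """Base class for all toolkit errors."""


class OntologyError(ArenosaeError):
    """Malformed ontology or template document."""


class DanglingReferenceError(OntologyError):
    """A term refers to a name that is not declared in the ontology."""

    def __init__(self, kind: str, name: str, context: str = ""):
        self.kind = kind
        self.name = name
        self.context = context
        msg = f"dangling {kind} reference: {name!r}"
        if context:
            msg += f" (in {context})"
        super().__init__(msg)


class DuplicateTermError(OntologyError):
    """Two terms of the same kind share a name."""

    def __init__(self, kind: str, name: str):
        self.kind = kind
        self.name = name
        super().__init__(f"duplicate {kind}: {name!r}")


class UnknownTermError(ArenosaeError):
    """A reference used a name the ontology does not define."""


class StructurePathError(ArenosaeError):
    """A structure path could not be resolved."""


class UnitError(ArenosaeError):
    """An unknown unit or an impossible unit conversion."""


class KeyDocumentError(ArenosaeError):
    """Structurally invalid identification key."""


class TreeFormatError(ArenosaeError):
    """Unreadable or inconsistent tree sample input."""


class NotUltrametricError(TreeFormatError):
    """A tree violates the ultrametricity tolerance."""

    def __init__(self, tip: str, deviation: float):
        self.tip = tip
        self.deviation = deviation
        super().__init__(
            f"tree is not ultrametric: tip {tip!r} deviates by {deviation:g} "
            "from the root-to-tip depth of the tree"
        )
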