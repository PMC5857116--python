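"""Exception hierarchy shared by the analysis modules."""


class StarMHError(Exception):
    """Base class for all package errors."""


class SchemaError(StarMHError):
    """A required column is absent or the column mapping is inconsistent."""


class IntegrityError(StarMHError):
    """Input data violate a uniqueness or consistency constraint."""


class DataValidationError(StarMHError):
    """Cell values or configuration fields are outside their legal domain."""


class DegenerateInputError(StarMHError):
    """The input is formally valid but the operation is undefined on it
    (e.g. a single-class outcome, an empty cohort after filtering)."""


class InestimableItemError(StarMHError):
    """An item has no response variation, so its difficulty cannot be
    estimated by conditional maximum likelihood."""

    def __init__(self, item_id: str, kind: str):
        self.item_id = item_id
        self.kind = kind
        super().__init__(
            f"item {item_id!r} has all-{kind} responses among non-extreme persons; "
            "its difficulty is not estimable"
        )


class IncompleteScreenError(StarMHError):
    """A scale answer is missing and the strict missing-data policy is active."""
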