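"""Exception types shared across modules."""


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


class RefAlleleMismatch(ValidationError):
    """An edit's stated reference base disagrees with the site sequence.

    Carries the in-site position plus both bases, guarding against
    coordinate-convention bugs between the variant and scoring layers.
    """

    def __init__(self, position: int, expected: str, found: str):
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"ref allele mismatch at in-site position {position}: "
            f"edit states {expected!r} but site sequence has {found!r}"
        )
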