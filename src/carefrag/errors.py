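"""Exception hierarchy for carefrag."""


class CarefragError(Exception):
    """Base class for all carefrag errors."""


class DatasetValidationError(CarefragError):
    """A table violates its schema or a row-level invariant.

    Carries a list of human-readable violation messages, each naming the
    table, row number (1-based, excluding the header) and column involved.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "dataset validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class IntegrityError(DatasetValidationError):
    """Referential integrity breach between tables (unknown ids)."""


class PatternError(CarefragError):
    """An ICD code pattern cannot be compiled (wildcard in an unsupported position)."""


class VocabularyError(CarefragError):
    """A named code set or drug class is missing from the vocabulary."""


class GeodesyError(CarefragError):
    """Invalid geodesy input (empty hospital list, bad coordinates)."""


class PhenotypeError(CarefragError):
    """A phenotype operation was called outside its precondition."""


class ConfigError(CarefragError):
    """Invalid study or generator configuration."""
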