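"""Exception hierarchy shared across the pipeline."""


class PhenorangesError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PhenorangesError):
    """Input file is missing a required column or the column map is invalid."""


class NoRecordsError(PhenorangesError):
    """Input file contains a header but no data rows (or nothing at all)."""


class StrainTableError(PhenorangesError):
    """Substrain-to-parent table violates the flat two-level invariant."""


class UnitMismatchError(PhenorangesError):
    """Records with different measurement units ended up in one stratum."""


class InsufficientStudiesError(PhenorangesError):
    """An operation needs more studies than the stratum provides."""


class DegenerateInputError(PhenorangesError):
    """All within-study variances are zero or a pooling denominator vanished."""


class CollinearityError(PhenorangesError):
    """Egger regression is undefined: all study precisions are identical."""


class PhenotypeMismatchError(PhenorangesError):
    """Two ranges being compared describe different phenotypes or units."""


class MissingRangeError(PhenorangesError):
    """A strain needed for control-range construction has no expected range."""


class KeyMismatchError(PhenorangesError):
    """Tool and expert label maps do not cover the same strain/phenotype keys."""
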