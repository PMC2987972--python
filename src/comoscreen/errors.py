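"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`ComoscreenError`,
split into configuration problems (bad YAML / bad parameters, CLI exit code 2)
and data problems (malformed tables, impossible values, CLI exit code 3).
"""


class ComoscreenError(Exception):
    """Base class for all errors raised by comoscreen."""


class ConfigError(ComoscreenError):
    """Invalid configuration: bad keys, bad parameter values, missing paths."""


class DataError(ComoscreenError):
    """Invalid data content (as opposed to invalid configuration)."""


class Icd9Error(DataError):
    """A diagnosis code that cannot be normalized to the canonical form."""


class SchemaError(DataError):
    """An input table is missing columns or violates a type/enum/uniqueness rule."""


class SeparationError(DataError):
    """A covariate completely separates cases from controls; the logistic MLE
    does not exist."""


class RankDeficiencyError(DataError):
    """The design matrix is rank deficient (constant or collinear covariates)."""


class ManifestError(DataError):
    """A simulation truth manifest is unreadable or has the wrong schema version."""
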