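"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`TripleWhammyError` so callers can
distinguish pipeline failures from programming errors.
"""


class TripleWhammyError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TripleWhammyError):
    """A source table is missing a mandatory column or has an unusable layout."""


class ValidationError(TripleWhammyError):
    """Input records violate a structural contract (e.g. duplicate case ids)."""


class ConfigurationError(TripleWhammyError):
    """A configuration object (drug lists, PT list, simulation config) is invalid."""


class DegenerateTableError(TripleWhammyError):
    """A 2x2 contingency table has a zero cell (or margin) that the chosen
    policy does not permit."""


class ConvergenceError(TripleWhammyError):
    """An iterative fit failed to converge within its iteration cap."""


class SeparationError(TripleWhammyError):
    """Logistic regression detected (quasi-)complete separation."""


class FitError(TripleWhammyError):
    """A distribution fit is impossible on the given sample (too small,
    zero spread, non-positive support)."""


class ImplausibleSequenceError(TripleWhammyError):
    """An event date precedes the exposure date it should follow."""
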