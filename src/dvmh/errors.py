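"""Exception hierarchy for the dvmh pipeline."""


class DvmhError(Exception):
    """Base class for all dvmh errors."""


class SchemaError(DvmhError):
    """A tabular input or mapping schema violates its contract."""


class DuplicateKeyError(DvmhError):
    """Two narratives share the same (event_id, narrative_id)."""


class ConfigError(DvmhError):
    """A resource (dictionary directory, rule file, generator config) is malformed."""


class ValidationError(DvmhError):
    """A loaded resource violates an invariant (empty dictionary, bad rule)."""


class UnmappedTermError(DvmhError):
    """A canonical disorder name matched no term group and carries no generic marker."""


class UndefinedMetricError(DvmhError):
    """A metric denominator is zero; the value is undefined, not silently 0."""


class InputError(DvmhError):
    """Inconsistent evaluation or aggregation inputs."""
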