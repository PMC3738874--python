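"""Exception types shared across the package."""


class DesignError(ValueError):
    """An invalid trial design or out-of-domain argument (exit code 1 in the CLI)."""


class ConfigurationError(ValueError):
    """Inconsistent user configuration, e.g. a futility threshold at or above
    the raise threshold, or an ill-specified adaptation rule."""


class DegenerateTableError(ValueError):
    """A logrank risk/event table whose variance term is zero — the statistic
    is undefined."""
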