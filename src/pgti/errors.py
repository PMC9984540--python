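"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration file or parameter set is inconsistent or incomplete."""


class StoppedProtonError(ValueError):
    """A proton stops before traversing the requested material thickness."""


class NonMonotoneMapError(ValueError):
    """A reference time map is not strictly monotone and cannot be inverted."""

    def __init__(self, detector_id, interval):
        self.detector_id = detector_id
        self.interval = interval
        super().__init__(
            f"reference map for detector {detector_id!r} is non-monotone "
            f"on [{interval[0]:.3f}, {interval[1]:.3f}] cm; an upstream detector "
            "whose gamma flight time shrinks faster than the proton transit time "
            "grows cannot be inverted event-by-event"
        )
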