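"""Shared condition and contrast vocabulary."""

CONTROL = "CONTROL"
RRMS = "RRMS"
PPMS = "PPMS"
SPMS = "SPMS"

MS_CONDITIONS = (RRMS, PPMS, SPMS)
CONDITIONS = (CONTROL,) + MS_CONDITIONS

#: contrast name -> MS condition compared against CONTROL
CONTRASTS = {
    "RRMS_vs_CONTROL": RRMS,
    "PPMS_vs_CONTROL": PPMS,
    "SPMS_vs_CONTROL": SPMS,
}


def contrast_condition(contrast: str) -> str:
    """Return the MS condition named by *contrast*, or raise ``ValueError``."""
    try:
        return CONTRASTS[contrast]
    except KeyError:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        ) from None
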