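"""Independent brute-force re-derivation of the attack classification rules.

Written directly from the clinical rules as plain conditionals on scalar
inputs, without touching the package's engine, so it can serve as an oracle
for exhaustive grid comparison.
"""

from __future__ import annotations


def oracle_label(
    duration_h: float,
    nrs: int,
    pulsating: bool,
    pressing: bool,
    one_sided: bool,
    both_sided: bool,
    aggravated: bool,
    aura: bool,
    nausea: bool,
    vomiting: bool,
    photophobia: bool,
    phonophobia: bool,
    triptan: bool | None = None,
    mig_history: bool = True,
    tth_history: bool = True,
) -> str:
    migraine = "MA" if aura else "MO"

    associated = nausea or vomiting or (photophobia and phonophobia)
    mod_or_severe = nrs >= 4
    mild_or_mod = 1 <= nrs <= 6

    mig_failures = 0
    if not (4.0 <= duration_h <= 72.0 or triptan is True):
        mig_failures += 1
    if (one_sided + pulsating + mod_or_severe + aggravated) < 2:
        mig_failures += 1
    if not associated:
        mig_failures += 1

    tth_failures = 0
    if not (0.5 <= duration_h <= 168.0):
        tth_failures += 1
    if (both_sided + pressing + mild_or_mod + (not aggravated)) < 2:
        tth_failures += 1
    if associated:
        tth_failures += 1

    if triptan is True:
        return migraine
    if duration_h < 0.5:
        return "NOT_CLASSIFIABLE"
    if mig_failures == 0:
        return migraine
    if tth_failures == 0:
        return "TTH"
    if mig_failures == 1 and mig_history:
        return migraine
    if tth_failures == 1 and tth_history:
        return "TTH"
    return "NOT_CLASSIFIABLE"
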