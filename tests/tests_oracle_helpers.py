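"""Independent oracle for the 5-tier combining table.

A literal, flat transcription of the combining rules, kept deliberately
separate from the package's boolean implementation so the two can be
compared by exhaustive enumeration.
"""

from sdhbcurate import FiveTierClass


def oracle_combine(vs, s, m, p, sa, bs, bp):
    pathogenic = any([
        vs >= 1 and s >= 1,
        vs >= 1 and m >= 1,
        vs >= 1 and p >= 2,
        vs >= 2,
        s >= 2,
        s >= 1 and m >= 3,
        s >= 1 and m == 2 and p >= 2,
        s >= 1 and m == 1 and p >= 4,
    ])
    likely_pathogenic = any([
        s == 1 and 1 <= m <= 2,
        s >= 1 and p >= 2,
        m >= 3,
        m == 2 and p >= 2,
        m == 1 and p >= 4,
    ])
    benign = sa >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2
    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return FiveTierClass.VUS
    if pathogenic:
        return FiveTierClass.PV
    if likely_pathogenic:
        return FiveTierClass.LPV
    if benign:
        return FiveTierClass.BV
    if likely_benign:
        return FiveTierClass.LBV
    return FiveTierClass.VUS
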