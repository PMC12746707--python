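"""Population-frequency tiers and ACMG/AMP classification for two variants.

Uses the published gnomAD count tables for the two candidate missense
variants and their ACMG evidence sets.
"""

import pandas as pd

from coseg.popfreq import (
    ACMGEvidence,
    acmg_combine,
    format_af,
    frequency_tier,
    load_frequency_table,
    zero_homozygote_flag,
)

counts = pd.DataFrame(
    {
        "variant": ["EHHADH", "EHHADH", "MASP1", "MASP1"],
        "population": ["overall", "european", "overall", "european"],
        "AC": [68, 59, 402, 319],
        "AN": [1_607_608, 1_175_130, 1_614_100, 1_180_040],
        "nhomalt": [0, 0, 0, 0],
    }
)
records = load_frequency_table(counts)

for rec in records:
    print(
        f"{rec.variant:7s} {rec.population:9s} AF = {format_af(rec.af)} "
        f"({rec.ac}/{rec.an:,}) -> {frequency_tier(rec.af)}"
    )
print(f"zero homozygotes in every population: {zero_homozygote_flag(records)}")
print()

for variant, codes in (("EHHADH", "PM1,PM2,PP2,PP3"), ("MASP1", "PM2,PP2,PP3")):
    evidence = ACMGEvidence.from_codes(codes)
    print(f"{variant:7s} {codes:17s} -> {acmg_combine(evidence).value}")
print()
print("Two moderate + two supporting criteria reach Likely Pathogenic; one")
print("moderate + two supporting stays a VUS under the combining rules.")
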