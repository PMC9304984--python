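"""Shared demographic constants: age bands, marital strata, need components."""

AGE_GROUPS: tuple[str, ...] = (
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
)

N_AGE_GROUPS = len(AGE_GROUPS)

AGE_INDEX = {a: i for i, a in enumerate(AGE_GROUPS)}

MARITAL_STATUSES: tuple[str, ...] = ("partnered", "unpartnered")

# Survey items required to classify need among non-users. A survey may lack
# any subset of these; the crosswalk adjusts estimates computed without them.
NEED_COMPONENTS: tuple[str, ...] = (
    "fecund",
    "wants_child_2yr",
    "ppa_status",
    "pregnancy_wanted",
)

# Quantities modelled on the proportion scale.
QUANTITY_CPR = "cpr"
QUANTITY_NEED_SHARE = "nonuser_need_share"
QUANTITY_PARTNERED = "partnered_proportion"

DEFAULT_YEARS: tuple[int, int] = (1970, 2019)
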