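"""Category systems shared across the pipeline."""

# Race/ethnicity categories mapping onto CDC WONDER groupings.
RACE_LEVELS: tuple[str, ...] = ("White", "Black", "Hispanic", "Other")
RACE_BASELINE: str = "White"

# Organ terms used in the search strategy and the story classifier.  Two-word
# organs are carried as a single compound token (underscore-joined).
ORGANS: tuple[str, ...] = (
    "kidney", "liver", "heart", "lung", "pancreas", "intestine", "bone_marrow",
)
SOLID_ORGANS: frozenset[str] = frozenset({"heart", "lung", "kidney", "liver", "pancreas"})

# Labels the classifier can emit beyond a single organ.
LABEL_MULTIPLE: str = "multiple"
LABEL_MISSING: str = "missing"

BASELINE_YEAR: int = 2015
STUDY_YEARS: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)

# Fraction of 2019 inside the study window (campaigns collected through March).
STUDY_2019_FRACTION: float = 0.25


def organ_query_term(organ: str) -> str:
    """Human-readable search term for an organ token ('bone_marrow' -> 'bone marrow')."""
    return organ.replace("_", " ")
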