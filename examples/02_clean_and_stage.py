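"""Clean a corrupted registry and build annualized severity transitions."""

from admarkov import CorruptionSpec, GeneratorParams, generate_registry
from admarkov.registry_prep import clean_registry, prepare_transitions

params = GeneratorParams(
    n_individuals=300, seed=2,
    corruption=CorruptionSpec(short_interval=5, duplicate_date=5,
                              after_death=5, missing_mmse=5),
)
registry = generate_registry(params)
clean, report = clean_registry(registry)
print("exclusions per cleaning rule:", report.counts)
print(f"kept {report.kept_rows} of {report.input_rows} rows")

transitions = prepare_transitions(clean)
observed = transitions[transitions["observed"]]
print(f"\n{len(observed)} annualized transitions; counts by follow-up year:")
print(observed.groupby("grid_year").size().head(6).to_string())
# Visits are interpolated onto each person's baseline-anchored annual grid
# (forward extrapolation at most 3 months), staged by MMSE, and paired
# into one-year state-to-state transitions; a death within a year of the
# last grid point becomes a transition to Death.
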