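"""Generate a synthetic longitudinal cohort and inspect its structure.

Builds the default two-cohort study (sparse-follow-up training cohort, dense
test cohort) and prints the session statistics the generator is tuned to.
"""

from cogage import SimulationConfig, generate_cohort

config = SimulationConfig(seed=1)
cohort = generate_cohort(config)

train = cohort.sessions_for("train")
test = cohort.sessions_for("test")
print(f"training cohort: {config.n_train} participants, {len(train)} sessions "
      f"({len(train) / config.n_train:.2f} per participant)")
print(f"test cohort:     {config.n_test} participants, {len(test)} sessions "
      f"({len(test) / config.n_test:.2f} per participant)")
print(f"age range across sessions: {cohort.sessions['age_at_session'].min():.1f}"
      f"–{cohort.sessions['age_at_session'].max():.1f} years")
print(f"tau-PET subsample: {cohort.roi['ftp_ec_suvr'].notna().sum()} "
      f"of {len(cohort.roi)} imaged participants")

# The mean sessions per participant emulate the real cohorts (1.56 and 4.79);
# the ROI table carries the planted group effects used further downstream.
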