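"""Full prioritization on a planted synthetic network.

Generates a modular network with five planted communicators wired to a
disease-gene module (plus 45 degree-matched decoys), calibrates the
significance threshold on the planted pathway modules, scores every
catalog entry against the disease genes, and reports the top hits.
"""

from itcwalk.pipeline import recovery_run

run = recovery_run(rng_seed=7)

print(f"calibrated significance threshold: {run.calibration.threshold:.4e}")
print(f"planted communicators: {', '.join(run.planted)}")
print("\ntop 5 normalized influence scores:")
col = run.scores.scores.iloc[:, 0].sort_values(ascending=False)
for itc, score in col.head(5).items():
    mark = "planted" if itc in run.planted else "decoy"
    print(f"  {itc}  {score:8.2f}  ({mark})")
print(f"\ntop-5 precision: {run.precision:.2f}")
print("\nA normalized score is the communicator's censored walk mass on the"
      " disease genes divided by the mean over random seed genes; values"
      " far above 1 mean influence beyond what network topology alone"
      " would give.")
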