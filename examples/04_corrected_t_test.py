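"""Corrected repeated-CV comparison along the weak-learner-count axis.

Evaluates the ensemble with 1..100 weak learners (a coarse grid here) and
the strong SVM on identical 5 x 10-fold partitions, applies the corrected
t statistic (df = 10) at every learner count, and Benjamini-Hochberg
adjusts the p-values across the grid.
"""

from nirspace import (
    SessionParams,
    build_feature_matrix,
    compare_over_learner_counts,
    preprocess_session,
    simulate_session,
)

params = SessionParams(seed=42, hrf_amplitude_hbo=0.005, hrf_amplitude_hbr=-0.002)
od, events = simulate_session(params)
fm = build_feature_matrix(preprocess_session(od, events), features=("AVG",), scheme=4)

comp = compare_over_learner_counts(
    fm, M=22, N=100, n_grid=[1, 2, 5, 10, 20, 50, 100], R=5, K=10, seed=1
)

print(f"strong SVM accuracy: {comp.strong_accuracy:.3f}")
print(" n    acc    t       p_fdr  sig")
for n, acc, test, p, sig in zip(
    comp.n_grid, comp.ensemble_accuracy, comp.tests, comp.p_fdr, comp.significant
):
    print(f"{n:3d}  {acc:.3f}  {test.t:+.3f}  {p:.4f}  {'*' if sig else ''}")

# Accuracy climbs steeply over the first ~20 weak learners and then
# saturates; a '*' marks counts where the ensemble's fold losses differ
# from the SVM's after FDR correction.  The corrected statistic divides by
# sqrt(S^2/11) regardless of the 50 fold pairs, so it is deliberately
# conservative about fold dependence.
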