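"""From raw optical density to the trials x D feature matrix.

Converts a simulated session to HbR/HbO with the modified Beer-Lambert
matrix, band-pass filters (0.01-0.09 Hz, zero phase), cuts -1..15 s epochs,
baseline-corrects against -1..0 s, and extracts windowed mean (AVG)
features on the fifteen 1 s windows (TYPE 4).
"""

from nirspace import (
    SessionParams,
    build_feature_matrix,
    preprocess_session,
    simulate_session,
    subset_size_ladder,
)

od, events = simulate_session(SessionParams(seed=42))
epochs = preprocess_session(od, events)
print(f"epochs: {epochs.data.shape} (trials x channels x [HbR, HbO] x samples)")
print(f"epoch time axis: {epochs.time_axis[0]:.2f} .. {epochs.time_axis[-1]:.2f} s")

fm = build_feature_matrix(epochs, features=("AVG",), scheme=4)
print(f"feature matrix: {fm.n_trials} trials x {fm.n_features} features")
print(f"first column: {fm.columns[0]}")
print(f"last column:  {fm.columns[-1]}")
print(f"subset-size ladder for D={fm.n_features}: {subset_size_ladder(fm.n_features)}")

# D = 1 feature type x 2 chromophores x 16 channels x 15 windows = 480;
# the ladder lists the candidate subset sizes for the ensemble's weak
# learners, centred at floor(sqrt(480) + 0.5) = 22.
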