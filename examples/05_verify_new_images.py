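"""Verify fresh micrographs before quantification.

Trains a verifier bundle on synthetic data, then classifies the same
field acquired in focus and badly defocused: the defocused acquisition
must be rejected so its wrong track count never enters the boron
quantification.
"""

from trackqc import classifiers, dataset, simulate, workflow

shape = (320, 416)
images = simulate.generate_dataset(120, fraction_adequate=0.5, rng_seed=20, shape=shape)
table = workflow.features_from_images(images)
balanced = dataset.balance_classes(table, rng_seed=21)
train_t, val_t, _ = dataset.split(balanced, rng_seed=22)
bundle = workflow.train_bundle(train_t, val_t, model="nn",
                               nn_config=classifiers.NNConfig(max_epochs=150, rng_seed=23))
print(f"trained NN bundle, operating threshold {bundle.threshold:.3f}")

pits = simulate.sample_pits(40, shape=shape, rng_seed=30)
good = simulate.render_image(pits, simulate.ADEQUATE, rng_seed=31, shape=shape)
bad = simulate.render_image(pits, simulate.AcquisitionCondition(defocus_sigma=2.0),
                            rng_seed=31, shape=shape)
for label, frame in [("in focus", good), ("defocused", bad)]:
    r = workflow.classify_image(frame.pixels, bundle)
    print(f"{label:>10}: P = {r.probability:.4f}, N = {r.track_count} tracks -> {r.decision}")
# only the in-focus acquisition's track count should be used downstream
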