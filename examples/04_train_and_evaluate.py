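"""Train and compare both quality-control classifiers on synthetic data.

Generates a labelled synthetic study, builds the 36-feature table,
preprocesses (drop / balance / split / PCA at 99.9% variance), then
trains the RBF SVM (randomized CV search) and the dense network, and
reports accuracy, AUC and the 97%-precision operating point.
"""

import numpy as np

from trackqc import classifiers, dataset, evaluation, simulate, workflow

images = simulate.generate_dataset(150, fraction_adequate=0.5, rng_seed=10, shape=(320, 416))
table = workflow.features_from_images(images)
balanced = dataset.balance_classes(table, rng_seed=11)
train_t, val_t, test_t = dataset.split(balanced, rng_seed=12)
train_t, val_t, test_t = (dataset.drop_uninformative(t) for t in (train_t, val_t, test_t))

pca = dataset.pca_fit(train_t, variance_target=0.999)
print(f"{pca.n_components} principal components keep 99.9% of the variance (of 34 features)")
x_tr, y_tr = classifiers.as_xy(train_t, dataset.pca_transform(pca, train_t))
x_va, y_va = classifiers.as_xy(val_t, dataset.pca_transform(pca, val_t))
x_te, y_te = classifiers.as_xy(test_t, dataset.pca_transform(pca, test_t))

svm, report = classifiers.svm_search_and_train(x_tr, y_tr, classifiers.SVMConfig(n_candidates=15, rng_seed=13))
print(f"SVM: best C={report.best_c:.2f}, gamma={report.best_gamma:.3f}, "
      f"cross-validated accuracy {100 * report.cv_accuracy:.1f}%")

nn = classifiers.nn_train(x_tr, y_tr, x_va, y_va, classifiers.NNConfig(max_epochs=200, rng_seed=14))
print(f"NN: stopped after {len(nn.history['epoch'])} epochs")

for name, model in [("SVM", svm), ("NN", nn)]:
    p = classifiers.predict(model, x_te)
    cm = evaluation.confusion(y_te, p, 0.5)
    _, _, auc = evaluation.roc_curve(y_te, p)
    print(f"{name}: test accuracy {100 * evaluation.accuracy(cm):.1f}%, AUC {auc:.3f}")

p_va = classifiers.predict(nn, x_va)
op = evaluation.select_threshold_for_precision(y_va, p_va, target=0.97)
print(f"NN operating point for 97% precision: threshold {op.threshold:.3f}, "
      f"recall {100 * op.recall:.1f}%")
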