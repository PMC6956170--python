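"""SA-SVM correcting its base SVM on the planted-misclassification fixture.

The fixture plants a few wrongly-side training labels (they end up in the
misclassified set MD) and test points inside those points' neighborhoods
where the base SVM is both wrong and unconfident.  The advising rule
overrides exactly those predictions.
"""

import numpy as np

from lsasvm import (KernelSpec, advised_predict, fit_sa_svm,
                    make_planted_fixture, predict, train_svm)

train, test, expected = make_planted_fixture(seed=1)
kernel = KernelSpec("rbf", gamma=train.metadata["gamma"])
base = train_svm(train, "c", kernel, train.metadata["C"])
adv = fit_sa_svm(base, train)

base_pred = predict(base, test.X)
adv_pred = advised_predict(adv, test.X)

print(f"misclassified training points (MD): {len(adv.md)}")
print(f"neighborhood lengths NL           : {np.round(adv.md.nl, 3)}")
print(f"base SVM test accuracy            : {np.mean(base_pred == test.y):.3f}")
print(f"SA-SVM test accuracy              : {np.mean(adv_pred == test.y):.3f}")
print(f"planted test indices              : {expected}")
print(f"  base predictions there          : {base_pred[expected]}")
print(f"  advised predictions there       : {adv_pred[expected]}  (true: {test.y[expected]})")

# Every planted point flips from the wrong base label to the correct one;
# the rest of the test set is untouched, so accuracy strictly improves.
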