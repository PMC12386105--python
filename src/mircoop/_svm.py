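"""Lean binary linear C-SVM fit.

The pipeline fits tens of thousands of tiny linear SVMs (one per miRNA
pair, plus five per candidate-module AUC evaluation), so the per-fit
overhead of the full estimator API dominates runtime.  This helper calls
scikit-learn's bundled libsvm binding directly and reconstructs
``(w, b)``; it is verified against ``SVC(kernel="linear")`` in the test
suite and falls back to the public estimator if the binding is
unavailable.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

try:  # scikit-learn's internal libsvm binding
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - exercised only on incompatible sklearn
    _libsvm = None


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Soft-margin linear C-SVM on binary 0/1 labels; returns (w, b).

    Decision rule: sign(w @ x + b), positive for class 1.
    """
    if _libsvm is not None:
        Xc = np.ascontiguousarray(X, dtype=np.float64)
        yc = np.ascontiguousarray(y, dtype=np.float64)
        _, SV, _, sv_coef, intercept, *_ = _libsvm.fit(
            Xc, yc, svm_type=0, kernel="linear", C=float(C), tol=1e-8
        )
        # libsvm orients the binary problem as class 0 vs 1; flip to match
        # the sklearn convention (class 1 on the positive side)
        return -(sv_coef @ SV).ravel(), -float(intercept[0])
    clf = SVC(kernel="linear", C=C).fit(X, y)  # pragma: no cover
    return clf.coef_[0].copy(), float(clf.intercept_[0])
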