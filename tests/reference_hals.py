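"""Independent oracles used by the tests.

These deliberately avoid the package's unfolding/Khatri-Rao code path:
the CP reconstruction oracle is a quadruple nested loop, the MTTKRP is
an einsum contraction against the raw 4D tensor, and the Gram matrix
uses the Hadamard-of-Grams identity. Agreement between these and the
package therefore checks the package's conventions, not just its
arithmetic.
"""

import numpy as np


def brute_force_reconstruct(contexts, lr, senders, receivers, weights=None):
    """Quadruple-loop evaluation of the rank-R CP sum."""
    c, p, s, t = (
        contexts.shape[0],
        lr.shape[0],
        senders.shape[0],
        receivers.shape[0],
    )
    rank = contexts.shape[1]
    if weights is None:
        weights = np.ones(rank)
    out = np.zeros((c, p, s, t))
    for i in range(c):
        for j in range(p):
            for k in range(s):
                for l in range(t):
                    total = 0.0
                    for r in range(rank):
                        total += (
                            weights[r]
                            * contexts[i, r]
                            * lr[j, r]
                            * senders[k, r]
                            * receivers[l, r]
                        )
                    out[i, j, k, l] = total
    return out


def brute_force_objective(model, pair, alphas):
    """Direct elementwise summation of the masked weighted objective."""
    total = 0.0
    for alpha, tensor, modality in (
        (alphas.alpha_a, pair.tensor_a, "a"),
        (alphas.alpha_b, pair.tensor_b, "b"),
    ):
        lr = model.lr_a if modality == "a" else model.lr_b
        w = model.weights_a if modality == "a" else model.weights_b
        hat = brute_force_reconstruct(
            model.contexts, lr, model.senders, model.receivers, w
        )
        c, p, s, t = tensor.values.shape
        for i in range(c):
            for j in range(p):
                for k in range(s):
                    for l in range(t):
                        if tensor.mask[i, j, k, l] == 1.0:
                            diff = tensor.values[i, j, k, l] - hat[i, j, k, l]
                            total += alpha * diff * diff
    return total


_LETTERS = "ijkl"


def single_tensor_hals_update(working, factors, mode, epsilon=1e-16):
    """Column-wise HALS update of one factor against one dense tensor.

    MTTKRP is computed by direct einsum contraction and the normal
    matrix by the Hadamard product of the other factors' Grams.
    """
    rank = factors[0].shape[1]
    others = [m for m in range(4) if m != mode]
    sub = ",".join(_LETTERS[m] + "r" for m in others)
    mttkrp = np.einsum(
        f"ijkl,{sub}->{_LETTERS[mode]}r",
        working,
        *[factors[m] for m in others],
        optimize=True,
    )
    gram = np.ones((rank, rank))
    for m in others:
        gram *= factors[m].T @ factors[m]
    updated = factors[mode].copy()
    for r in range(rank):
        if gram[r, r] <= 0:
            continue
        updated[:, r] = np.maximum(
            epsilon,
            updated[:, r] + (mttkrp[:, r] - updated @ gram[:, r]) / gram[r, r],
        )
    return updated


def single_tensor_cp_fit(values, mask, init_factors, n_sweeps, epsilon=1e-16):
    """Masked non-negative CP via EM imputation + HALS, fixed sweep count.

    ``init_factors`` is [contexts, lr, senders, receivers]; updates run
    in that order each sweep.
    """
    factors = [f.copy() for f in init_factors]
    for _ in range(n_sweeps):
        hat = np.einsum(
            "ir,jr,kr,lr->ijkl", *factors, optimize=True
        )
        working = mask * values + (1.0 - mask) * hat
        for mode in range(4):
            factors[mode] = single_tensor_hals_update(
                working, factors, mode, epsilon
            )
    return factors
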