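"""Independent naive trace of the learning model, used as a likelihood oracle.

Deliberately re-derives every quantity from the printed formulas with plain
``math`` scalar arithmetic and an explicit per-orientation dictionary — no
code is shared with the package's implementation.
"""

import math


def naive_similarity(d, width, kernel):
    if kernel == "gaussian":
        return math.exp(-(d * d) / (2.0 * width * width))
    return math.exp(-abs(d) / (2.0 * width * width))


def naive_trace(params, trials, exclude_unsure=False, update_invalid=True):
    """Step-by-step trace of a trial sequence.

    ``params``: dict with s_i, s_e, beta, a, alpha_train, alpha_test, kernel.
    ``trials``: list of dicts with phase, orientation, outcome, response,
    valid.  Returns (records, total_loglik) where each record holds V, p,
    delta and the loglik term (None if the trial is not scored).
    """
    E = {}
    I = {}
    total = 0.0
    records = []
    for tr in trials:
        x = tr["orientation"]
        v = 0.0
        for xj in E:
            v += E[xj] * naive_similarity(xj - x, params["s_e"], params["kernel"])
        for xj in I:
            v -= I[xj] * naive_similarity(xj - x, params["s_i"], params["kernel"])
        p = 1.0 / (1.0 + math.exp(-params["beta"] * (v - params["a"])))
        term = None
        if tr["valid"] and not (exclude_unsure and tr["response"] == "unsure"):
            term = math.log(p) if tr["response"] == "plus" else math.log(1.0 - p)
            total += term
        delta = tr["outcome"] - v
        records.append({"V": v, "p": p, "delta": delta, "loglik_term": term})
        if tr["valid"] or update_invalid:
            alpha = (
                params["alpha_train"] if tr["phase"] == "training" else params["alpha_test"]
            )
            if delta > 0:
                E[x] = E.get(x, 0.0) + alpha * delta
            elif delta < 0:
                I[x] = I.get(x, 0.0) - alpha * delta
    return records, total
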