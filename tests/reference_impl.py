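"""Independent reference implementations used as oracles by the tests.

Deliberately naive and structurally different from the library kernels:
the literal-year reference is a straight week-by-week transcription of the
state equations with dictionary bookkeeping; the conserving reference
enumerates every individual pathway (diagnosis week x treatment-entry
week) and sums the probabilities directly.
"""

from __future__ import annotations


def naive_literal_year(cfg: dict, counts, prev_open: float):
    """Spreadsheet-style stepping of the literal weekly equations.

    ``cfg`` is a plain dict with keys: retention, f_diag, f_treat, f_open,
    f_closed, carryover, d1, d2, d3, weeks.  Lagged look-ups before week 0
    resolve to zero.  Returns a list of dicts, one per week 0..weeks.
    """
    weeks = cfg["weeks"]
    rows = []
    pi0 = cfg["carryover"] * prev_open
    rows.append(
        {
            "Pi": pi0,
            "Pd": 0.0,
            "Ptr": 0.0,
            "Poc": cfg["f_open"] * pi0 + cfg["f_closed"] * 0.0,
        }
    )

    def lookup(col, week):
        if week < 0:
            return 0.0
        return rows[week][col]

    for n in range(1, weeks + 1):
        pi = cfg["retention"] * counts[n - 1] + rows[n - 1]["Pi"]
        pd_ = cfg["retention"] * (
            rows[n - 1]["Pd"] + cfg["f_diag"] * lookup("Pi", n - cfg["d1"])
        )
        ptr = rows[n - 1]["Ptr"] + cfg["f_treat"] * lookup("Pd", n - cfg["d2"])
        rows.append({"Pi": pi, "Pd": pd_, "Ptr": ptr, "Poc": 0.0})
        rows[n]["Poc"] = cfg["f_open"] * pi + cfg["f_closed"] * lookup(
            "Ptr", n - cfg["d3"]
        )
    return rows


def enumerate_conserving_expectation(cfg: dict, cohorts):
    """Exact expected weekly head-counts by pathway enumeration.

    ``cohorts`` is a list of ``(arrival_week, mass)`` pairs where the mass
    has already passed intake dropout (week 0 entries model the annual
    carryover).  ``cfg`` keys: r1, r2, f_open, f_closed, d1, d2, L, weeks.

    Pathway semantics: first diagnosis attempt at ``arrival + d1`` with
    per-week success probability r1; first treatment-entry attempt at
    ``diagnosis + d2`` with probability r2; a fixed L-week treatment spell
    closing at ``entry + L``, after which a fraction f_closed stays on the
    open-case register; at the final week, still-undiagnosed mass moves to
    open cases with fraction f_open and diagnosed-but-untreated mass moves
    there entirely.
    """
    W = cfg["weeks"]
    r1, r2 = cfg["r1"], cfg["r2"]
    d1, d2, L = cfg["d1"], cfg["d2"], cfg["L"]
    Pi = [0.0] * (W + 1)
    Pd = [0.0] * (W + 1)
    Ptr = [0.0] * (W + 1)
    Poc = [0.0] * (W + 1)

    for w, mass in cohorts:
        # probability of being undiagnosed at the end of week n
        def p_undiag(n):
            if n < w + d1:
                return 1.0
            return (1.0 - r1) ** (n - (w + d1) + 1)

        for n in range(w, W):  # week W: everyone re-evaluated out of Pi
            Pi[n] += mass * p_undiag(n)
        p_never = p_undiag(W)
        Poc[W] += mass * cfg["f_open"] * p_never

        for t in range(w + d1, W + 1):
            p_t = r1 * (1.0 - r1) ** (t - (w + d1))

            def p_not_entered(n):
                if n < t + d2:
                    return 1.0
                return (1.0 - r2) ** (n - (t + d2) + 1)

            for n in range(t, W):
                Pd[n] += mass * p_t * p_not_entered(n)
            Poc[W] += mass * p_t * p_not_entered(W)

            for u in range(t + d2, W + 1):
                p_u = p_t * r2 * (1.0 - r2) ** (u - (t + d2))
                close = u + L
                for n in range(u, min(close - 1, W) + 1):
                    Ptr[n] += mass * p_u
                if close <= W:
                    for n in range(close, W + 1):
                        Poc[n] += mass * p_u * cfg["f_closed"]
    return {"S_Pi": Pi, "S_Pd": Pd, "S_Ptr": Ptr, "S_Poc": Poc}
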