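"""Independent straight-line oracles used to check the package.

Everything here is written with plain Python loops and ``math`` so it
shares no code path with the implementation under test.
"""

import math


def oracle_scale(xs):
    lo, hi = min(xs), max(xs)
    if hi == lo:
        return [0.0 for _ in xs]
    return [(x - lo) / (hi - lo) for x in xs]


def oracle_pci(columns, specs, threat_weights, interaction_weights):
    """Transcription of the index pipeline.

    Parameters
    ----------
    columns : dict name -> list of raw values (one per species)
    specs : dict name -> (role, direction, transform)
    threat_weights : dict threat name -> w
    interaction_weights : dict (threat, modifier) -> z
    """
    n_sp = len(next(iter(columns.values())))
    scaled = {}
    for name, raw in columns.items():
        role, direction, transform = specs[name]
        vals = list(raw)
        if transform == "log1p":
            vals = [math.log(1.0 + v) for v in vals]
        vals = oracle_scale(vals)
        if direction == "inverted":
            vals = [1.0 - v for v in vals]
        scaled[name] = vals

    threats = [n for n in columns if specs[n][0] == "threat"]
    r = {}
    for ti in threats:
        mods = {vj: z for (t, vj), z in interaction_weights.items() if t == ti}
        if not mods:
            r[ti] = list(scaled[ti])
        else:
            r[ti] = [
                sum(z * scaled[ti][s] * scaled[vj][s] for vj, z in mods.items())
                for s in range(n_sp)
            ]

    fs_r = {ti: oracle_scale(r[ti]) for ti in threats}
    wsum = sum(threat_weights[ti] for ti in threats)
    agg = [
        sum(threat_weights[ti] * fs_r[ti][s] for ti in threats) / wsum
        for s in range(n_sp)
    ]
    return oracle_scale(agg)
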