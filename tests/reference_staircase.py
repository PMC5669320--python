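"""Independent brute-force transcription of the adaptive stepping rules.

Deliberately written as one flat loop with explicit branches, separate from
the package engine, so the two can be compared trial-for-trial.  Conventions
transcribed: n consecutive correct responses -> one step harder, any error ->
one step easier; step factor chosen by the number of reversals already
recorded; a reversal is logged when the logical step direction differs from
the previous step's direction (the first step only sets direction); the
reversal value is the value presented on the direction-flip trial; clamping
at the floor/ceiling does not change the logical direction; terminate at the
target reversal count.
"""


def reference_track(responses, start, factors, n_up, harder,
                    floor=None, ceiling=None, total_reversals=8):
    """Replay a response sequence through the rules.

    responses: iterable of booleans (correct / incorrect)
    harder: 'increase' or 'decrease' (which way the harder direction moves)

    Returns a dict with the per-trial log and the reversal values.  Stops
    early once the reversal count is reached; leftover responses are ignored.
    """
    value = start
    ncorr = 0
    prev_dir = None
    reversals = []
    log = []  # (trial, value, correct, reversal_flag, factor)

    trial = 0
    for correct in responses:
        if len(reversals) >= total_reversals:
            break
        trial += 1
        presented = value
        factor = factors[len(reversals)] if len(reversals) < len(factors) else factors[-1]

        move = None
        if correct:
            ncorr = ncorr + 1
            if ncorr == n_up:
                ncorr = 0
                move = 'H'
        else:
            ncorr = 0
            move = 'E'

        flag = False
        if move is not None:
            if harder == 'increase':
                nxt = presented * factor if move == 'H' else presented / factor
            else:
                nxt = presented / factor if move == 'H' else presented * factor
            if floor is not None and nxt < floor:
                nxt = floor
            if ceiling is not None and nxt > ceiling:
                nxt = ceiling
            if prev_dir is not None and move != prev_dir:
                flag = True
                reversals.append(presented)
            prev_dir = move
            value = nxt

        log.append((trial, presented, bool(correct), flag, factor))

    return {"log": log, "reversals": reversals,
            "terminated": len(reversals) >= total_reversals}
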