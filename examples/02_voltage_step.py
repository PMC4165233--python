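"""Simulate the somatic step protocol on the reference cell.

Assembles the control morphology with the default channel complement,
measures its input resistance with the hyperpolarizing pulse, injects the
0.35 nA reference step, and classifies the response from the first
interspike interval.
"""

from dendrofire import (
    build_cell_spec,
    classify_firing,
    control_cell,
    detect_spikes,
    discretize,
    measure_input_resistance,
    run,
    step_protocol,
)

graph = discretize(build_cell_spec(control_cell()))
rin = measure_input_resistance(graph)
print(f"input resistance: {rin:.1f} MOhm")

trace = run(graph, step_protocol(0.35, t_on_ms=20.0, dur_ms=1000.0),
            dt=0.025)
spikes = detect_spikes(trace)
label = classify_firing(spikes)
print(f"spikes: {len(spikes)}, first ISI: {label.first_isi:.2f} ms")
print(f"firing category: {label.category}")

# IB means the first two spikes are closer than 20 ms (an onset burst);
# RS means regular spiking from the start; the control cell is tuned to
# sit near that boundary so that dendritic load tips it either way.
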