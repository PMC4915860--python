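"""Simulate a paced human ventricular action potential and describe it.

Runs the ten Tusscher-Panfilov 2006 epicardial model for one 1 Hz cycle,
samples Vm every 0.2 ms, and extracts the six AP shape biomarkers.
"""

import cardiouq as cq
from cardiouq.biomarkers import extract

model = cq.get_model("tentusscher_2006_epi")
protocol = cq.make_protocol("single_ap")  # one -52 pA/pF x 1 ms stimulus, 1000 ms window
trace = cq.run(model, None, protocol)

b = extract(trace)
print(f"samples: {len(trace)} at {trace.sample_interval} ms")
print(f"resting Vm : {b.resting_vm:8.2f} mV   (diastolic potential before the stimulus)")
print(f"max dVm/dt : {b.max_dvdt:8.2f} mV/ms (upstroke velocity)")
print(f"max Vm     : {b.max_vm:8.2f} mV   (spike overshoot)")
print(f"dome Vm    : {b.dome_vm:8.2f} mV   (plateau after the epicardial notch)")
print(f"APD50      : {b.apd50:8.2f} ms   (time to 50% repolarisation)")
print(f"APD90      : {b.apd90:8.2f} ms   (time to 90% repolarisation)")
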