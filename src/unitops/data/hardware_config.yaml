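# Default virtual-hardware model.
#
# Geometry matches the instrument: 3 reactors, 3 cassettes x 11 vials,
# 5 gasket sealing stations plus the off-gasket install position.
# Kinetic values (heater ramp, per-verb motion costs, evaporation rate) are
# model parameters of the simulator, not measured instrument constants.

n_reactors: 3
vessel_capacity_mL: 5.0       # must exceed the largest simultaneous load
ambient_C: 25.0
ramp_C_per_s: 2.0             # heater/chiller ramp toward set-point
evap_rate_mL_per_s: 0.005     # volume removed while the evaporation path is active
f18_delivery_mL: 1.0          # cyclotron target-water bolus pushed through the QMA
f18_activity_units: 1.0       # relative starting activity carried by the bolus
external_add_fraction: 1.0    # fraction of a declared vial delivered by EXTERNALADD

# simulated seconds consumed by each verb (WAIT/WAIT_TEMP computed instead)
verb_durations_s:
  MOVE_REACTOR: 5.0
  GRIPPER_MOVE: 3.0
  RAISE_SEAL: 2.0
  LOWER_VESSEL: 2.0
  PICK_VIAL: 2.0
  PLACE_VIAL: 2.0
  RETURN_VIAL: 4.0
  SET_VALVE: 0.25
  SET_PRESSURE: 0.25
  SET_TEMP: 0.0
  SET_STIR: 0.0
  USER_WAIT: 0.0
  LOG: 0.0
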