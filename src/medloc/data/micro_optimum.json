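{
 "gamma": 1000.0,
 "multipliers": [
  44268.75508158191,
  1.0
 ],
 "increasing_factor": 1.0,
 "weighted_travel": true,
 "set_members": [
  "M2",
  "M7"
 ],
 "augmented_capacities": [
  159637.27230769233,
  129322.72769230769
 ],
 "capacity_investment": 0.09778410958904123,
 "n_assignments": 256,
 "best_assignment": {
  "M1": "M2",
  "M2": "M2",
  "M3": "M2",
  "M4": "M2",
  "M5": "M7",
  "M6": "M7",
  "M7": "M7",
  "M8": "M7"
 },
 "best_total_cost": 272018.46498092095,
 "best_travel_cost": 285699.41042258963,
 "best_capacity_cost": 0.0523858092249845,
 "best_spatial_cost": -16000.0
}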