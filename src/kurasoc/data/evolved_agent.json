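{
 "network": {
  "natural_frequencies_rad_s": [
   1.2903225806451613,
   3.548387096774194,
   1.4516129032258065
  ],
  "preferred_phase_relations_rad": [
   0.7600627387717243,
   -0.8614044372746207,
   0.6587210402688277
  ],
  "plasticity_rates_per_s": [
   [
    0.0,
    0.8709677419354839,
    0.26129032258064516
   ],
   [
    0.8419354838709677,
    0.0,
    0.6387096774193549
   ],
   [
    0.4064516129032258,
    0.3774193548387097,
    0.0
   ]
  ],
  "coupling_gains": [
   2.5806451612903225,
   2.4193548387096775,
   2.096774193548387
  ],
  "h1_rad": 0.6283185307179586,
  "h2_rad": 0.6283185307179586
 },
 "body": {
  "sensor_gains_rAlArBlB": [
   -3.354838709677419,
   6.96774193548387,
   -8.0,
   4.387096774193548
  ],
  "motor_bias_right_rad": 3.2429343520926897,
  "motor_bias_left_rad": 1.0134169850289656,
  "radius_units": 4.0
 },
 "meta": {
  "genome": [
   0,
   1,
   0,
   0,
   0,
   1,
   0,
   1,
   1,
   0,
   0,
   1,
   0,
   0,
   1,
   0,
   1,
   0,
   0,
   1,
   1,
   1,
   1,
   0,
   1,
   0,
   0,
   0,
   0,
   0,
   1,
   1,
   0,
   0,
   0,
   1,
   0,
   0,
   0,
   0,
   0,
   1,
   1,
   1,
   1,
   0,
   1,
   1,
   0,
   1,
   1,
   1,
   1,
   1,
   0,
   0,
   1,
   0,
   0,
   1,
   1,
   1,
   1,
   0,
   1,
   1,
   0,
   1,
   1,
   0,
   0,
   1,
   1,
   1,
   0,
   0,
   1,
   1,
   0,
   1,
   1,
   0,
   0,
   0,
   0,
   0,
   0,
   1,
   0,
   1,
   1,
   0,
   1,
   1,
   1,
   0,
   0,
   1,
   1,
   1,
   1,
   0,
   1,
   1,
   0
  ],
  "provenance": "behavioural-preference GA",
  "ga_seed": 4,
  "generations": 100,
  "population": 20,
  "final_generation_best_fitness": 0.42241755105972306,
  "best_fitness_overall": 0.5700715969589333,
  "selection": "best individual of the GA's final generation; chosen among independent GA runs (seeds 1-8) as the agent displaying the task's target phenotype: stable but switching light preferences with run-to-run consistent scaling"
 }
}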