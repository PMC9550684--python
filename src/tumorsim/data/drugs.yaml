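# Default drug library.
#
# All values are literature-order defaults authored for this package (PK
# half-lives and distribution volumes on clinical scales; kill/IC50 chosen
# on the tissue-concentration scale the simulator produces).  They are NOT
# measurements from any single study and every field is overridable via a
# user library file or per-case sensitivity multipliers.
#
# Units: k_el, k12, k21, kill_max in 1/h; V_d in L; IC50 in mg/L;
# D (tissue diffusion) in mm^2/h; relative_permeability scales Ktrans.
drugs:
  doxorubicin:
    k_el: 0.035
    V_d: 25.0
    n_compartments: 2
    k12: 0.8
    k21: 0.15
    kill_max: 0.060
    IC50: 1.0
    hill: 1.5
    relative_permeability: 0.03
    D: 0.3
  cyclophosphamide:
    k_el: 0.10
    V_d: 30.0
    kill_max: 0.040
    IC50: 5.0
    hill: 1.0
    relative_permeability: 0.03
    D: 0.5
  paclitaxel:
    k_el: 0.08
    V_d: 100.0
    kill_max: 0.050
    IC50: 0.5
    hill: 1.2
    relative_permeability: 0.03
    D: 0.3
  docetaxel:
    k_el: 0.06
    V_d: 80.0
    kill_max: 0.050
    IC50: 0.5
    hill: 1.2
    relative_permeability: 0.03
    D: 0.3
  carboplatin:
    k_el: 0.25
    V_d: 16.0
    kill_max: 0.040
    IC50: 10.0
    hill: 1.0
    relative_permeability: 0.03
    D: 0.6
  trastuzumab:
    k_el: 0.0041
    V_d: 3.0
    kill_max: 0.010
    IC50: 100.0
    hill: 1.0
    relative_permeability: 0.006
    D: 0.05
    growth_multiplier: 0.5
  pertuzumab:
    k_el: 0.0016
    V_d: 3.0
    kill_max: 0.005
    IC50: 200.0
    hill: 1.0
    relative_permeability: 0.006
    D: 0.05
    growth_multiplier: 0.7
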