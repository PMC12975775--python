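# Default 17-item SDOH codebook: five HHS domains, ordered-categorical
# categories listed from most advantaged to most disadvantaged, continuous
# items on their instrument's theoretical bounds. `reverse: true` marks
# instruments that score advantage high (flipped during unit scoring).
version: "1"
items:
  # --- economic stability -------------------------------------------------
  - name: annual_income
    domain: economic_stability
    kind: ordered_categorical
    categories:
      - "More than 200k"
      - "150k-200k"
      - "100k-150k"
      - "75k-100k"
      - "50k-75k"
      - "25k-50k"
      - "Less than 25k"
  - name: employed_for_wages
    domain: economic_stability
    kind: ordered_categorical
    categories: ["Yes", "No"]
  - name: home_ownership
    domain: economic_stability
    kind: ordered_categorical
    categories: ["Own", "Rent", "Other arrangement"]
  - name: food_insecurity
    domain: economic_stability
    kind: ordered_categorical
    categories: ["No", "Yes"]
  - name: housing_quality_problem
    domain: economic_stability
    kind: ordered_categorical
    categories: ["No", "Yes"]
  # --- education ----------------------------------------------------------
  - name: education_years
    domain: education
    kind: ordered_categorical
    categories:
      - "Advanced Degree"
      - "College Graduate"
      - "College One to Three"
      - "Under Twelve Or GED"
  # --- health care access and quality --------------------------------------
  - name: health_insurance
    domain: healthcare_access_quality
    kind: ordered_categorical
    categories: ["Yes", "No"]
  - name: discrimination_in_health
    domain: healthcare_access_quality
    kind: continuous
    scale_min: 0.0
    scale_max: 1.0
  # --- neighborhood and built environment -----------------------------------
  - name: neighborhood_physical_disorder
    domain: neighborhood_built_environment
    kind: continuous
    scale_min: 0.0
    scale_max: 1.0
  - name: neighborhood_social_disorder
    domain: neighborhood_built_environment
    kind: continuous
    scale_min: 0.0
    scale_max: 1.0
  - name: neighborhood_walkability
    domain: neighborhood_built_environment
    kind: continuous
    scale_min: 1.0
    scale_max: 4.0
    reverse: true
  - name: neighborhood_safety
    domain: neighborhood_built_environment
    kind: continuous
    scale_min: 1.0
    scale_max: 4.0
    reverse: true
  # --- social and community context -----------------------------------------
  - name: social_cohesion
    domain: social_community_context
    kind: continuous
    scale_min: 1.0
    scale_max: 5.0
    reverse: true
  - name: social_support
    domain: social_community_context
    kind: continuous
    scale_min: 1.0
    scale_max: 5.0
    reverse: true
  - name: loneliness
    domain: social_community_context
    kind: continuous
    scale_min: 0.0
    scale_max: 1.0
  - name: perceived_discrimination
    domain: social_community_context
    kind: continuous
    scale_min: 0.0
    scale_max: 1.0
  - name: perceived_stress
    domain: social_community_context
    kind: continuous
    scale_min: 0.0
    scale_max: 1.0
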