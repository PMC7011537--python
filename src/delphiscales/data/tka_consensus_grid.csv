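goal_id,scale_id,round,top_pct
preventing_secondary_impairments,three_point,1,82.8
preventing_secondary_impairments,five_point,1,69.0
preventing_secondary_impairments,nine_point,1,90.8
preventing_secondary_impairments,three_point,2,85.1
preventing_secondary_impairments,five_point,2,70.1
preventing_secondary_impairments,nine_point,2,89.7
duration_of_hospitalization,three_point,1,52.9
duration_of_hospitalization,five_point,1,36.8
duration_of_hospitalization,nine_point,1,64.4
duration_of_hospitalization,three_point,2,48.3
duration_of_hospitalization,five_point,2,39.1
duration_of_hospitalization,nine_point,2,62.1
stability,three_point,1,94.3
stability,five_point,1,79.3
stability,nine_point,1,97.7
stability,three_point,2,96.6
stability,five_point,2,81.6
stability,nine_point,2,96.6
pain,three_point,1,89.7
pain,five_point,1,79.3
pain,nine_point,1,95.4
pain,three_point,2,95.4
pain,five_point,2,79.3
pain,nine_point,2,94.3
implant_survival,three_point,1,79.3
implant_survival,five_point,1,75.9
implant_survival,nine_point,1,89.7
implant_survival,three_point,2,86.2
implant_survival,five_point,2,73.6
implant_survival,nine_point,2,83.9
quality_of_life,three_point,1,87.4
quality_of_life,five_point,1,73.6
quality_of_life,nine_point,1,97.7
quality_of_life,three_point,2,89.7
quality_of_life,five_point,2,74.7
quality_of_life,nine_point,2,90.8
range_of_motion,three_point,1,92.0
range_of_motion,five_point,1,80.5
range_of_motion,nine_point,1,96.6
range_of_motion,three_point,2,93.1
range_of_motion,five_point,2,79.3
range_of_motion,nine_point,2,96.6
activities_of_daily_living,three_point,1,86.2
activities_of_daily_living,five_point,1,78.2
activities_of_daily_living,nine_point,1,94.3
activities_of_daily_living,three_point,2,89.7
activities_of_daily_living,five_point,2,77.0
activities_of_daily_living,nine_point,2,88.5
malalignment,three_point,1,66.7
malalignment,five_point,1,47.1
malalignment,nine_point,1,72.4
malalignment,three_point,2,63.2
malalignment,five_point,2,46.0
malalignment,nine_point,2,72.4
strength,three_point,1,79.3
strength,five_point,1,60.9
strength,nine_point,1,93.1
strength,three_point,2,80.5
strength,five_point,2,65.5
strength,nine_point,2,92.0
employability,three_point,1,54.0
employability,five_point,1,35.6
employability,nine_point,1,64.4
employability,three_point,2,56.3
employability,five_point,2,47.1
employability,nine_point,2,65.5
walking_stairs,three_point,1,86.2
walking_stairs,five_point,1,74.7
walking_stairs,nine_point,1,92.0
walking_stairs,three_point,2,89.7
walking_stairs,five_point,2,77.0
walking_stairs,nine_point,2,89.7
walking_distance,three_point,1,93.1
walking_distance,five_point,1,75.9
walking_distance,nine_point,1,96.6
walking_distance,three_point,2,92.0
walking_distance,five_point,2,75.9
walking_distance,nine_point,2,94.3
no_side_effects,three_point,1,78.2
no_side_effects,five_point,1,67.8
no_side_effects,nine_point,1,83.9
no_side_effects,three_point,2,74.7
no_side_effects,five_point,2,71.3
no_side_effects,nine_point,2,82.8
participation_in_social_life,three_point,1,82.8
participation_in_social_life,five_point,1,65.5
participation_in_social_life,nine_point,1,89.7
participation_in_social_life,three_point,2,81.6
participation_in_social_life,five_point,2,60.9
participation_in_social_life,nine_point,2,87.4
sex_life,three_point,1,20.7
sex_life,five_point,1,17.2
sex_life,nine_point,1,31.0
sex_life,three_point,2,19.5
sex_life,five_point,2,20.7
sex_life,nine_point,2,29.9
physical_function,three_point,1,83.9
physical_function,five_point,1,64.4
physical_function,nine_point,1,90.8
physical_function,three_point,2,85.1
physical_function,five_point,2,70.1
physical_function,nine_point,2,93.1
physical_activity,three_point,1,71.3
physical_activity,five_point,1,59.8
physical_activity,nine_point,1,88.5
physical_activity,three_point,2,70.1
physical_activity,five_point,2,70.1
physical_activity,nine_point,2,80.5
global_health_status,three_point,1,90.8
global_health_status,five_point,1,73.6
global_health_status,nine_point,1,94.3
global_health_status,three_point,2,89.7
global_health_status,five_point,2,79.3
global_health_status,nine_point,2,92.0
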