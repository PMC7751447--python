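item_id,stratum,word_en,in_20_item_form
low_02,low,Eye,0
low_06,low,Fiber,1
low_08,low,Meat,1
low_12,low,Heart,0
low_13,low,Blood,1
low_15,low,Hospital,1
low_16,low,Vision,0
low_17,low,Snack,0
low_19,low,Insulin,1
low_20,low,Alcohol,1
low_23,low,Diet,1
low_27,low,Nerve,0
low_28,low,Cut,0
low_29,low,Sore,0
medium_01,medium,Dizzy,0
medium_02,medium,Fatigue,1
medium_08,medium,Fluid,1
medium_09,medium,Portion,1
medium_13,medium,Calorie,0
medium_14,medium,Infection,0
medium_15,medium,Stroke,1
medium_16,medium,Fasting,0
medium_17,medium,Glucose,1
medium_19,medium,Nutrition,0
medium_20,medium,Vegetable,1
medium_22,medium,Swelling,0
medium_23,medium,Sweating,0
medium_24,medium,Appointment,1
high_02,high,Circulation,0
high_04,high,Hypoglycemia,0
high_05,high,Endocrinologist,1
high_10,high,Hyperglycemia,1
high_11,high,Dialysis,1
high_13,high,Prescription,1
high_14,high,Amputation,1
high_15,high,Pharmacist,0
high_16,high,Medication,0
high_17,high,Lancet,0
high_18,high,Pancreas,0
high_25,high,Hemoglobin A1C,1
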