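code,description,ccsr_category,synonyms
A150,Tuberculosis of lung,Tuberculosis,
A419,"Sepsis, unspecified organism",Septicemia,sepsis
B181,Chronic viral hepatitis B,Viral hepatitis,
B509,"Plasmodium falciparum malaria, unspecified",Malaria,malaria
C50911,Malignant neoplasm of unspecified site of right female breast,Breast cancer,breast cancer
C50912,Malignant neoplasm of unspecified site of left female breast,Breast cancer,
C50919,Malignant neoplasm of unspecified site of unspecified female breast,Breast cancer,
C9290,"Myeloid leukemia, unspecified, not having achieved remission",Leukemia,myeloid leukemia
C719,"Malignant neoplasm of brain, unspecified",Brain cancer,brain tumor|brain cancer
C189,"Malignant neoplasm of colon, unspecified",Colorectal cancer,colon cancer
E119,Type 2 diabetes mellitus without complications,Diabetes mellitus without complication,diabetes
E109,Type 1 diabetes mellitus without complications,Diabetes mellitus without complication,
E039,"Hypothyroidism, unspecified",Thyroid disorders,
E6601,Morbid severe obesity due to excess calories,Obesity,
E559,"Vitamin D deficiency, unspecified",Nutritional deficiencies,
F329,"Major depressive disorder, single episode, unspecified",Depressive disorders,depression
F419,"Anxiety disorder, unspecified",Anxiety and fear-related disorders,anxiety
F1020,"Alcohol dependence, uncomplicated",Alcohol-related disorders,
F209,"Schizophrenia, unspecified",Schizophrenia spectrum disorders,
F840,Autistic disorder,Autism spectrum disorders,autism
G20,Parkinson disease,Parkinson disease,
G35,Multiple sclerosis,Multiple sclerosis,
G40909,"Epilepsy, unspecified, not intractable, without status epilepticus",Epilepsy,epilepsy
G1221,Amyotrophic lateral sclerosis,Spinal muscular atrophy,
G439,"Migraine, unspecified, not intractable",Migraine,
I671,"Cerebral aneurysm, nonruptured",Cerebral aneurysm,brain aneurysm
I219,"Acute myocardial infarction, unspecified",Acute myocardial infarction,heart attack
I509,"Heart failure, unspecified",Heart failure,
I10,Essential primary hypertension,Essential hypertension,high blood pressure
I6350,"Cerebral infarction, unspecified",Cerebral infarction,stroke
J449,"Chronic obstructive pulmonary disease, unspecified",Chronic obstructive pulmonary disease,copd
J45909,"Unspecified asthma, uncomplicated",Asthma,
J189,"Pneumonia, unspecified organism",Pneumonia,
J9601,Acute respiratory failure with hypoxia,Respiratory failure,
J329,"Chronic sinusitis, unspecified",Sinusitis,
K7030,Alcoholic cirrhosis of liver without ascites,Alcoholic liver disease,
K509,"Crohn disease, unspecified, without complications",Inflammatory bowel disease,crohns disease
K219,Gastro esophageal reflux disease without esophagitis,Esophageal disorders,acid reflux
K8590,"Acute pancreatitis without necrosis or infection, unspecified",Pancreatitis,
K3580,Unspecified acute appendicitis,Appendicitis,
M169,"Osteoarthritis of hip, unspecified",Osteoarthritis,
M069,"Rheumatoid arthritis, unspecified",Rheumatoid arthritis,
M5450,"Low back pain, unspecified",Back problems,
M329,"Systemic lupus erythematosus, unspecified",Lupus,lupus
M810,Age related osteoporosis without current pathological fracture,Osteoporosis,
N186,End stage renal disease,Chronic kidney disease,kidney failure
N179,"Acute kidney failure, unspecified",Acute renal failure,
N390,"Urinary tract infection, site not specified",Urinary tract infections,
N200,Calculus of kidney,Nephrolithiasis,kidney stones
N400,Benign prostatic hyperplasia without lower urinary tract symptoms,Benign prostatic hyperplasia,enlarged prostate
S72001A,Fracture of unspecified part of neck of right femur initial encounter,Hip fracture,broken hip
S82101A,Unspecified fracture of upper end of right tibia initial encounter,Lower limb fracture,broken leg
S42001A,Fracture of unspecified part of right clavicle initial encounter,Shoulder fracture,broken collarbone
S060X0A,Concussion without loss of consciousness initial encounter,Concussion,concussion
S2240XA,Unspecified fracture of one rib unspecified side initial encounter,Rib fracture,broken ribs
H2513,Age related nuclear cataract bilateral,Cataract,cataracts
D649,"Anemia, unspecified",Anemias,anemia
O219,"Vomiting of pregnancy, unspecified",Maternal care,
L409,"Psoriasis, unspecified",Psoriasis,
R569,Unspecified convulsions,Convulsions,
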