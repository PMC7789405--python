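canonical_name,drug_class,treats
atorvastatin,hmg-coa reductase inhibitor,ldl
simvastatin,hmg-coa reductase inhibitor,ldl
rosuvastatin,hmg-coa reductase inhibitor,ldl
pravastatin,hmg-coa reductase inhibitor,ldl
lovastatin,hmg-coa reductase inhibitor,ldl
fluvastatin,hmg-coa reductase inhibitor,ldl
pitavastatin,hmg-coa reductase inhibitor,ldl
ezetimibe,cholesterol absorption inhibitor,ldl
colesevelam,bile acid sequestrant,ldl
cholestyramine,bile acid sequestrant,ldl
colestipol,bile acid sequestrant,ldl
fenofibrate,fibric acid derivative,ldl
gemfibrozil,fibric acid derivative,ldl
niacin,nicotinic acid derivative,ldl
alirocumab,pcsk9 inhibitor,ldl
evolocumab,pcsk9 inhibitor,ldl
lisinopril,ace inhibitor,bp
enalapril,ace inhibitor,bp
ramipril,ace inhibitor,bp
benazepril,ace inhibitor,bp
captopril,ace inhibitor,bp
quinapril,ace inhibitor,bp
fosinopril,ace inhibitor,bp
losartan,angiotensin receptor blocker,bp
valsartan,angiotensin receptor blocker,bp
irbesartan,angiotensin receptor blocker,bp
olmesartan,angiotensin receptor blocker,bp
candesartan,angiotensin receptor blocker,bp
telmisartan,angiotensin receptor blocker,bp
metoprolol,beta blocker,bp
atenolol,beta blocker,bp
carvedilol,beta blocker,bp
bisoprolol,beta blocker,bp
propranolol,beta blocker,bp
nebivolol,beta blocker,bp
labetalol,beta blocker,bp
amlodipine,calcium channel blocker,bp
nifedipine,calcium channel blocker,bp
diltiazem,calcium channel blocker,bp
verapamil,calcium channel blocker,bp
felodipine,calcium channel blocker,bp
hydrochlorothiazide,thiazide diuretic,bp
chlorthalidone,thiazide diuretic,bp
indapamide,thiazide diuretic,bp
furosemide,loop diuretic,bp
spironolactone,aldosterone antagonist,bp
clonidine,central alpha agonist,bp
hydralazine,vasodilator,bp
doxazosin,alpha blocker,bp
metformin,biguanide,a1c
glipizide,sulfonylurea,a1c
glyburide,sulfonylurea,a1c
glimepiride,sulfonylurea,a1c
pioglitazone,thiazolidinedione,a1c
rosiglitazone,thiazolidinedione,a1c
sitagliptin,dpp-4 inhibitor,a1c
saxagliptin,dpp-4 inhibitor,a1c
linagliptin,dpp-4 inhibitor,a1c
empagliflozin,sglt2 inhibitor,a1c
canagliflozin,sglt2 inhibitor,a1c
dapagliflozin,sglt2 inhibitor,a1c
liraglutide,glp-1 receptor agonist,a1c
exenatide,glp-1 receptor agonist,a1c
dulaglutide,glp-1 receptor agonist,a1c
semaglutide,glp-1 receptor agonist,a1c
insulin glargine,insulin,a1c
insulin lispro,insulin,a1c
insulin aspart,insulin,a1c
insulin detemir,insulin,a1c
acarbose,alpha-glucosidase inhibitor,a1c
repaglinide,meglitinide,a1c
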